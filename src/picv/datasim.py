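"""Balanced case-control genotype simulation from a penetrance model.

Emulates GAMETES-style instance generation: genotypes are drawn under
Hardy-Weinberg and linkage equilibrium, status follows the penetrance
table, and the balanced sampler draws exactly n/2 cases and n/2 controls
directly from the analytic case/control conditional genotype
distributions

    P(cell ij | case)    = f_ij p_ij / K
    P(cell ij | control) = f_ij (1 - p_ij) / (1 - K),

which is equivalent in distribution to rejection sampling from the
population but runs in deterministic time even at low prevalence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .penetrance import PenetranceModel, joint_genotype_probs, population_prevalence

__all__ = [
    "GenotypeDataset",
    "simulate_balanced_dataset",
    "simulate_population",
    "write_dataset",
    "read_dataset",
    "read_plink_raw",
]

logger = logging.getLogger(__name__)


@dataclass
class GenotypeDataset:
    """Per-individual SNP doses, binary status, and optional covariates."""

    snp1: np.ndarray
    snp2: np.ndarray
    status: np.ndarray
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.snp1 = np.asarray(self.snp1, dtype=np.int64)
        self.snp2 = np.asarray(self.snp2, dtype=np.int64)
        self.status = np.asarray(self.status, dtype=np.int64)
        n = len(self.snp1)
        if len(self.snp2) != n or len(self.status) != n:
            raise ValueError("snp1, snp2 and status must have equal length")
        for name, col in (("snp1", self.snp1), ("snp2", self.snp2)):
            if col.size and not np.isin(col, (0, 1, 2)).all():
                raise ValueError(f"{name} doses must lie in {{0, 1, 2}}")
        if self.status.size and not np.isin(self.status, (0, 1)).all():
            raise ValueError("status must be binary 0/1")
        if self.covariates is not None:
            if len(self.covariates) != n:
                raise ValueError("covariates must have one row per individual")
            self.covariates = self.covariates.reset_index(drop=True)

    @property
    def n(self) -> int:
        return len(self.snp1)

    def subset(self, idx: np.ndarray) -> "GenotypeDataset":
        cov = None if self.covariates is None else self.covariates.iloc[idx]
        return GenotypeDataset(self.snp1[idx], self.snp2[idx], self.status[idx], cov)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"snp1": self.snp1, "snp2": self.snp2, "status": self.status}
        )
        if self.covariates is not None:
            df = pd.concat([df, self.covariates.reset_index(drop=True)], axis=1)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenotypeDataset":
        required = {"snp1", "snp2", "status"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"dataset is missing columns: {sorted(missing)}")
        extra = [c for c in df.columns if c not in required]
        cov = df[extra].reset_index(drop=True) if extra else None
        return cls(
            df["snp1"].to_numpy(),
            df["snp2"].to_numpy(),
            df["status"].to_numpy(),
            cov,
        )


def _cell_conditionals(model: PenetranceModel) -> tuple[np.ndarray, np.ndarray, float]:
    f = joint_genotype_probs(model)
    k = population_prevalence(model)
    if not 0 < k < 1:
        raise ValueError(
            f"model '{model.label}' is degenerate: prevalence {k} admits no "
            "case-control sampling"
        )
    case = f * model.pen / k
    control = f * (1 - model.pen) / (1 - k)
    return case, control, k


def _draw_cells(probs: np.ndarray, n: int, rng: np.random.Generator):
    counts = rng.multinomial(n, probs.ravel()).reshape(3, 3)
    snp1 = np.repeat(np.repeat([0, 1, 2], 3), counts.ravel())
    snp2 = np.repeat(np.tile([0, 1, 2], 3), counts.ravel())
    return snp1, snp2


def simulate_balanced_dataset(
    model: PenetranceModel, n: int, rng: np.random.Generator
) -> GenotypeDataset:
    """Draw a balanced case-control dataset of total size ``n`` (n/2 each).

    Case genotypes are multinomial over the case-conditional cell
    distribution, controls over the control-conditional one; rows are
    shuffled so position carries no information.
    """
    if n < 2 or n % 2:
        raise ValueError(f"total sample size must be even and >= 2, got {n}")
    case_p, control_p, _ = _cell_conditionals(model)
    half = n // 2
    s1_case, s2_case = _draw_cells(case_p, half, rng)
    s1_ctrl, s2_ctrl = _draw_cells(control_p, half, rng)
    snp1 = np.concatenate([s1_case, s1_ctrl])
    snp2 = np.concatenate([s2_case, s2_ctrl])
    status = np.concatenate([np.ones(half, dtype=int), np.zeros(half, dtype=int)])
    order = rng.permutation(n)
    return GenotypeDataset(snp1[order], snp2[order], status[order])


def simulate_population(
    model: PenetranceModel, n: int, rng: np.random.Generator
) -> GenotypeDataset:
    """Draw ``n`` individuals from the population model.

    Genotypes follow the HWE joint distribution and status is Bernoulli
    with the cell penetrance, so the case fraction converges to the
    model prevalence.  Useful for prevalence checks and for calibrating
    tests under a known generative model.
    """
    if n < 1:
        raise ValueError(f"sample size must be >= 1, got {n}")
    f = joint_genotype_probs(model)
    snp1, snp2 = _draw_cells(f, n, rng)
    order = rng.permutation(n)
    snp1, snp2 = snp1[order], snp2[order]
    status = (rng.random(n) < model.pen[snp1, snp2]).astype(int)
    return GenotypeDataset(snp1, snp2, status)


def write_dataset(dataset: GenotypeDataset, path, sep: str = "\t") -> None:
    """Write a dataset as delimited text (columns snp1, snp2, status, covariates)."""
    dataset.to_frame().to_csv(path, sep=sep, index=False)


def read_dataset(path, sep: str | None = None) -> GenotypeDataset:
    """Read a delimited-text dataset; the delimiter is sniffed when not given."""
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    return GenotypeDataset.from_frame(df)


def read_plink_raw(path, snp_columns: tuple[str, str] | None = None) -> GenotypeDataset:
    """Read a PLINK ``.raw`` (``--recode A``) additive-coded genotype file.

    The header is ``FID IID PAT MAT SEX PHENOTYPE`` followed by SNP
    columns coded 0/1/2.  PHENOTYPE 1/2 is mapped to control/case (0/1).
    ``snp_columns`` selects the two SNP columns by name; by default the
    first two SNP columns are used.  Rows with a missing genotype or
    phenotype are dropped (count logged).
    """
    df = pd.read_csv(path, sep=r"\s+")
    meta = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    if df.columns[: len(meta)].tolist() != meta:
        raise ValueError(f"not a PLINK .raw header: {df.columns[:6].tolist()}")
    snp_cols = list(snp_columns) if snp_columns else [c for c in df.columns[6:]][:2]
    if len(snp_cols) != 2 or any(c not in df.columns for c in snp_cols):
        raise ValueError(f"need two SNP columns, got {snp_cols}")
    sub = df[["PHENOTYPE", *snp_cols]].apply(pd.to_numeric, errors="coerce")
    keep = sub.notna().all(axis=1) & sub["PHENOTYPE"].isin([1, 2])
    dropped = int((~keep).sum())
    if dropped:
        logger.info("read_plink_raw: dropped %d rows with missing data", dropped)
    sub = sub[keep]
    return GenotypeDataset(
        sub[snp_cols[0]].to_numpy(dtype=int),
        sub[snp_cols[1]].to_numpy(dtype=int),
        (sub["PHENOTYPE"].to_numpy(dtype=int) - 1),
    )
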