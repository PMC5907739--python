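"""Two-locus penetrance models and their Hardy-Weinberg algebra.

A penetrance model is the generative core of a two-SNP epistasis
simulation: two minor allele frequencies plus a 3x3 table giving
``P(case | SNP1 dose = i, SNP2 dose = j)``.  Under Hardy-Weinberg
equilibrium and linkage equilibrium between the loci, the model implies
genotype frequencies, a population prevalence ``K`` and a (broad-sense,
penetrance-variance) heritability

    h2 = sum_ij f_ij (p_ij - K)^2 / (K (1 - K)),

which is how epistasis simulators such as GAMETES quantify the signal
strength of a table.

Fifteen prevalence-0.5 models used throughout the package's evaluation
harness are bundled as a plain-text YAML fixture and available through
:func:`load_builtin_models`.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

__all__ = [
    "PenetranceModel",
    "hwe_genotype_probs",
    "joint_genotype_probs",
    "population_prevalence",
    "model_heritability",
    "marginal_penetrances",
    "load_builtin_models",
    "read_model",
    "write_model",
]

_BUILTIN_FIXTURE = "builtin_models.yaml"
_BUILTIN_SHA256 = "8642a10ca91263ed248e072917de135b6edaf120de7b41967eaa9c4ba0cb9b9b"


@dataclass(frozen=True)
class PenetranceModel:
    """Two MAFs plus a 3x3 penetrance matrix.

    ``pen[i, j]`` is the probability of case status given ``i`` minor
    alleles at SNP1 and ``j`` at SNP2 (rows index SNP1 dose).
    """

    maf1: float
    maf2: float
    pen: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        pen = np.asarray(self.pen, dtype=float)
        if pen.shape != (3, 3):
            raise ValueError(f"penetrance matrix must be 3x3, got {pen.shape}")
        if np.any(pen < 0) or np.any(pen > 1):
            raise ValueError("penetrance entries must lie in [0, 1]")
        for name, maf in (("maf1", self.maf1), ("maf2", self.maf2)):
            if not 0 < maf <= 0.5:
                raise ValueError(f"{name} must lie in (0, 0.5], got {maf}")
        object.__setattr__(self, "pen", pen)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PenetranceModel):
            return NotImplemented
        return (
            self.maf1 == other.maf1
            and self.maf2 == other.maf2
            and self.label == other.label
            and np.array_equal(self.pen, other.pen)
        )


def hwe_genotype_probs(maf: float) -> np.ndarray:
    """Genotype dose probabilities ((1-q)^2, 2q(1-q), q^2) under HWE.

    ``maf`` may be 0 (monomorphic limit) but not exceed 0.5, so that the
    dose always counts the minor allele.
    """
    if not 0 <= maf <= 0.5:
        raise ValueError(f"minor allele frequency must lie in [0, 0.5], got {maf}")
    q = float(maf)
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q * q])


def joint_genotype_probs(model: PenetranceModel) -> np.ndarray:
    """3x3 joint genotype frequencies, the outer product of the two HWE margins."""
    return np.outer(hwe_genotype_probs(model.maf1), hwe_genotype_probs(model.maf2))


def population_prevalence(model: PenetranceModel) -> float:
    """Marginal case probability K = sum_ij f_ij * pen_ij."""
    return float(np.sum(joint_genotype_probs(model) * model.pen))


def model_heritability(model: PenetranceModel) -> float:
    """Penetrance-variance heritability sum_ij f_ij (pen_ij - K)^2 / (K(1-K))."""
    f = joint_genotype_probs(model)
    k = float(np.sum(f * model.pen))
    if not 0 < k < 1:
        raise ValueError(f"prevalence must lie strictly in (0, 1), got {k}")
    return float(np.sum(f * (model.pen - k) ** 2) / (k * (1 - k)))


def marginal_penetrances(model: PenetranceModel) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus marginal penetrances.

    Returns ``(m1, m2)`` where ``m1[i] = sum_j P(SNP2=j) pen[i, j]`` is
    the case probability given SNP1 dose ``i`` (and symmetrically for
    ``m2``).  A model with no marginal effect at a locus has a flat
    margin there.
    """
    w1 = hwe_genotype_probs(model.maf1)
    w2 = hwe_genotype_probs(model.maf2)
    return model.pen @ w2, model.pen.T @ w1


def _model_from_mapping(entry: dict) -> PenetranceModel:
    return PenetranceModel(
        maf1=float(entry["maf1"]),
        maf2=float(entry["maf2"]),
        pen=np.asarray(entry["pen"], dtype=float),
        label=str(entry.get("label", "")),
    )


def load_builtin_models() -> list[PenetranceModel]:
    """The 15 bundled prevalence-0.5 penetrance models, in scenario order.

    The fixture file is digest-checked so silent corruption of the
    bundled numbers raises rather than propagating into simulations.
    """
    ref = resources.files("picv.data").joinpath(_BUILTIN_FIXTURE)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _BUILTIN_SHA256:
        raise RuntimeError(
            f"bundled model fixture is corrupted (sha256 {digest}, "
            f"expected {_BUILTIN_SHA256})"
        )
    entries = yaml.safe_load(raw)["models"]
    models = [_model_from_mapping(e) for e in entries]
    if len(models) != 15:
        raise RuntimeError(f"expected 15 bundled models, found {len(models)}")
    return models


def read_model(path) -> PenetranceModel:
    """Read a penetrance model from a YAML file with keys maf1, maf2, pen[, label]."""
    with open(path) as fh:
        entry = yaml.safe_load(fh)
    return _model_from_mapping(entry)


def write_model(model: PenetranceModel, path) -> None:
    """Write a model to YAML, round-trippable through :func:`read_model`."""
    payload = {
        "label": model.label,
        "maf1": model.maf1,
        "maf2": model.maf2,
        "pen": [[float(x) for x in row] for row in model.pen],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
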