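# The 15 two-SNP penetrance models used for the prevalence-0.5 simulations.
# pen rows are indexed by SNP1 minor-allele dose, columns by SNP2 dose.
models:
- label: Scenario 1
  maf1: 0.1
  maf2: 0.1
  pen:
  - [0.493, 0.526, 0.611]
  - [0.531, 0.387, 0.008]
  - [0.522, 0.410, 0.358]
- label: Scenario 2
  maf1: 0.2
  maf2: 0.1
  pen:
  - [0.507, 0.471, 0.485]
  - [0.480, 0.590, 0.532]
  - [0.556, 0.249, 0.482]
- label: Scenario 3
  maf1: 0.2
  maf2: 0.2
  pen:
  - [0.514, 0.467, 0.539]
  - [0.481, 0.544, 0.447]
  - [0.425, 0.674, 0.304]
- label: Scenario 4
  maf1: 0.3
  maf2: 0.1
  pen:
  - [0.513, 0.438, 0.520]
  - [0.494, 0.530, 0.475]
  - [0.456, 0.696, 0.506]
- label: Scenario 5
  maf1: 0.3
  maf2: 0.2
  pen:
  - [0.488, 0.527, 0.478]
  - [0.525, 0.455, 0.458]
  - [0.450, 0.562, 0.814]
- label: Scenario 6
  maf1: 0.3
  maf2: 0.3
  pen:
  - [0.481, 0.525, 0.483]
  - [0.533, 0.468, 0.470]
  - [0.446, 0.513, 0.734]
- label: Scenario 7
  maf1: 0.4
  maf2: 0.1
  pen:
  - [0.484, 0.570, 0.545]
  - [0.501, 0.494, 0.551]
  - [0.535, 0.359, 0.245]
- label: Scenario 8
  maf1: 0.4
  maf2: 0.2
  pen:
  - [0.490, 0.512, 0.565]
  - [0.523, 0.468, 0.395]
  - [0.455, 0.568, 0.668]
- label: Scenario 9
  maf1: 0.4
  maf2: 0.3
  pen:
  - [0.502, 0.499, 0.495]
  - [0.523, 0.472, 0.503]
  - [0.425, 0.588, 0.501]
- label: Scenario 10
  maf1: 0.4
  maf2: 0.4
  pen:
  - [0.476, 0.506, 0.536]
  - [0.535, 0.473, 0.503]
  - [0.449, 0.568, 0.410]
- label: Scenario 11
  maf1: 0.5
  maf2: 0.1
  pen:
  - [0.306, 0.428, 0.322]
  - [0.333, 0.314, 0.198]
  - [0.341, 0.256, 0.595]
- label: Scenario 12
  maf1: 0.5
  maf2: 0.2
  pen:
  - [0.476, 0.521, 0.715]
  - [0.521, 0.472, 0.392]
  - [0.482, 0.536, 0.502]
- label: Scenario 13
  maf1: 0.5
  maf2: 0.3
  pen:
  - [0.500, 0.477, 0.608]
  - [0.520, 0.480, 0.482]
  - [0.459, 0.563, 0.429]
- label: Scenario 14
  maf1: 0.5
  maf2: 0.4
  pen:
  - [0.422, 0.548, 0.531]
  - [0.515, 0.491, 0.492]
  - [0.547, 0.470, 0.485]
- label: Scenario 15
  maf1: 0.5
  maf2: 0.5
  pen:
  - [0.440, 0.522, 0.515]
  - [0.560, 0.484, 0.472]
  - [0.440, 0.509, 0.542]
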