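# Single-Dispersal (SD) out-of-Africa model: one African source ghost
# (G1) spawns a single emigrant population (the non-African stem, G2) at
# tdOA1; Australo-Melanesians (P) branch from the stem at tOAbot1, Basal
# Eurasians (BE) at tdG2BE, and Europeans/Asians at tdEA.  The archaic
# scaffold is identical to the MD model.  45 free parameters: the MD set
# minus the second ghost lineage (tdYG2), the second exit block (tdOA2,
# tOAbot2) and the two ancient-window rates tied to the G2/EA coexistence
# window (m1G2EA, m1EAG2).
name: SD
description: >
  Single-dispersal out-of-Africa scenario; all non-Africans derive from
  one emigrant stem, with the same archaic admixture structure as MD.
populations: [N, D, Y, E, A, P, AR, D1, D2, NR, G1, G2, BE, YG, NNR, D12, DDR, DN, ADN, AM]
sampled:
  N: 120000
  D: 72000
  Y: 0
  E: 0
  A: 0
  P: 0
fixed:
  tNNR: 150000
  tD12: 250000
  tDDR: 300000
  tDN: 415000
  tADN: 590000
  tAM: 655000
  nBot: 250
priors:
  nAR:  {dist: uniform, low: 100, high: 50000}
  nY:   {dist: uniform, low: 100, high: 50000}
  nG1:  {dist: uniform, low: 100, high: 50000}
  nG2:  {dist: uniform, low: 100, high: 50000}
  nBE:  {dist: uniform, low: 100, high: 50000}
  nE:   {dist: uniform, low: 100, high: 50000}
  nA:   {dist: uniform, low: 100, high: 50000}
  nP:   {dist: uniform, low: 100, high: 50000}
  nYG:  {dist: uniform, low: 100, high: 50000}
  nNNR: {dist: uniform, low: 100, high: 50000}
  nDDR: {dist: uniform, low: 100, high: 50000}
  nDN:  {dist: uniform, low: 100, high: 50000}
  nADN: {dist: uniform, low: 100, high: 50000}
  nAM:  {dist: uniform, low: 100, high: 50000}
  rP:   {dist: uniform, low: 0.01, high: 0.1}
  rEA:  {dist: uniform, low: 0.01, high: 0.1}
  tdYG1:   {dist: uniform, low: 50000, high: 145000}
  tdOA1:   {dist: uniform, low: 45000, high: 125000}
  tOAbot1: {dist: uniform, low: 40000, high: 125000}
  tdG2BE:  {dist: uniform, low: 50000, high: 120000}
  tdEA:    {dist: uniform, low: 30000, high: 52000}
  taNG2:   {dist: uniform, low: 42000, high: 75000}
  taNEA:   {dist: uniform, low: 33000, high: 58000}
  taARP:   {dist: uniform, low: 37000, high: 110000}
  taD1P:   {dist: uniform, low: 30000, high: 100000}
  taD2A:   {dist: uniform, low: 20000, high: 43000}
  taBEE:   {dist: uniform, low: 10000, high: 47000}
  paNG2: {dist: uniform, low: 0.0, high: 0.1}
  paNEA: {dist: uniform, low: 0.0, high: 0.1}
  paARP: {dist: uniform, low: 0.0, high: 0.1}
  paD1P: {dist: uniform, low: 0.0, high: 0.1}
  paD2A: {dist: uniform, low: 0.0, high: 0.1}
  paBEE: {dist: uniform, low: 0.0, high: 0.5}
  mYG1:  {dist: uniform, low: 0.0, high: 0.001}
  mG1Y:  {dist: uniform, low: 0.0, high: 0.001}
  mG1G2: {dist: uniform, low: 0.0, high: 0.001}
  mG2G1: {dist: uniform, low: 0.0, high: 0.001}
  mG2E:  {dist: uniform, low: 0.0, high: 0.001}
  mEG2:  {dist: uniform, low: 0.0, high: 0.001}
  mEA:   {dist: uniform, low: 0.0, high: 0.001}
  mAE:   {dist: uniform, low: 0.0, high: 0.001}
  mAP:   {dist: uniform, low: 0.0, high: 0.001}
  mPA:   {dist: uniform, low: 0.0, high: 0.001}
  m1EAP:  {dist: uniform, low: 0.0, high: 0.001}
  m1PEA:  {dist: uniform, low: 0.0, high: 0.001}
sizes:
  N: nNNR
  NR: nNNR
  NNR: nNNR
  D: nDDR
  D1: nDDR
  D2: nDDR
  D12: nDDR
  DDR: nDDR
  DN: nDN
  AR: nAR
  ADN: nADN
  AM: nAM
  YG: nYG
  Y: nY
  G1: nG1
  G2: nG2
  BE: nBE
  E: nE
  A: nA
  P: nP
growth:
  - {population: P, rate: rP, modern_size: nP, bottleneck_time: tOAbot1, founder_size: nBot}
  # the emigrant stem (G2) is founded at the exit bottleneck and recovers
  # towards its modern size at rate rEA
  - {population: G2, rate: rEA, modern_size: nG2, bottleneck_time: tdOA1, founder_size: nBot}
events:
  # modern structure (backward in time): E/A and P branch from the stem G2
  - {type: divergence, time: tdEA, derived: [E, A], ancestral: G2}
  - {type: divergence, time: tOAbot1, derived: [P], ancestral: G2}
  - {type: divergence, time: tdG2BE, derived: [BE], ancestral: G2}
  - {type: divergence, time: tdOA1, derived: [G2], ancestral: G1, label: out_of_africa}
  - {type: divergence, time: tdYG1, derived: [Y, G1], ancestral: YG}
  # archaic scaffold (identical to MD)
  - {type: divergence, time: tNNR, derived: [N, NR], ancestral: NNR}
  - {type: divergence, time: tD12, derived: [D1, D2], ancestral: D12}
  - {type: divergence, time: tDDR, derived: [D, D12], ancestral: DDR}
  - {type: divergence, time: tDN, derived: [NNR, DDR], ancestral: DN}
  - {type: divergence, time: tADN, derived: [AR, DN], ancestral: ADN}
  - {type: divergence, time: tAM, derived: [YG, ADN], ancestral: AM}
  # admixture pulses: both Neandertal pulses enter the stem, the first just
  # after the exit (before P branches), the second into the Eurasian
  # ancestor (after P branches)
  - {type: pulse, time: taNG2, source: NR, dest: G2, proportion: paNG2}
  - {type: pulse, time: taNEA, source: NR, dest: G2, proportion: paNEA}
  - {type: pulse, time: taARP, source: AR, dest: P, proportion: paARP}
  - {type: pulse, time: taD1P, source: D1, dest: P, proportion: paD1P}
  - {type: pulse, time: taD2A, source: D2, dest: A, proportion: paD2A}
  - {type: pulse, time: taBEE, source: BE, dest: E, proportion: paBEE}
  # continuous migration windows
  - {type: migration, rate: mYG1, source: Y, dest: G1, start: 0, end: tdYG1}
  - {type: migration, rate: mG1Y, source: G1, dest: Y, start: 0, end: tdYG1}
  - {type: migration, rate: mG1G2, source: G1, dest: G2, start: 0, end: tdOA1}
  - {type: migration, rate: mG2G1, source: G2, dest: G1, start: 0, end: tdOA1}
  - {type: migration, rate: mG2E, source: G2, dest: E, start: 0, end: tdEA}
  - {type: migration, rate: mEG2, source: E, dest: G2, start: 0, end: tdEA}
  - {type: migration, rate: mEA, source: E, dest: A, start: 0, end: tdEA}
  - {type: migration, rate: mAE, source: A, dest: E, start: 0, end: tdEA}
  - {type: migration, rate: mAP, source: A, dest: P, start: 0, end: tdEA}
  - {type: migration, rate: mPA, source: P, dest: A, start: 0, end: tdEA}
  # ancient window between the Eurasian split and P's branching
  - {type: migration, rate: m1EAP, source: G2, dest: P, start: tdEA, end: tOAbot1}
  - {type: migration, rate: m1PEA, source: P, dest: G2, start: tdEA, end: tOAbot1}
constraints:
  - tOAbot1 < tdOA1
  - tdOA1 < tdYG1
  - tdEA < tOAbot1
  - tdG2BE < tdOA1
  - taNG2 < tdOA1
  - tOAbot1 < taNG2
  - tdEA < taNEA
  - taNEA < tOAbot1
  - taARP < tOAbot1
  - taD1P < tOAbot1
  - taD2A < tdEA
  - taBEE < tdEA
  - taBEE < tdG2BE
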