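# Multiple-Dispersal (MD) out-of-Africa model: two African source
# populations (ghosts G1, G2) give rise to two waves of emigrants, the
# first founding the Australo-Melanesians (P), the second the Eurasians
# (EA -> E, A).  Shared archaic scaffold: an unknown archaic population
# (AR), three Denisovan demes (D sampled, D1/D2 introgressing) and two
# Neandertal demes (N sampled, NR introgressing).  Times in years,
# sizes in diploids, migration rates per generation.  50 free parameters.
name: MD
description: >
  Multiple-dispersal out-of-Africa scenario with Basal Eurasian (BE)
  contribution to Europeans, archaic admixture pulses and continuous
  migration among contemporary demes.
populations: [N, D, Y, E, A, P, AR, D1, D2, NR, G1, G2, BE, EA, YG, NNR, D12, DDR, DN, ADN, AM]
sampled:
  N: 120000
  D: 72000
  Y: 0
  E: 0
  A: 0
  P: 0
fixed:
  tNNR: 150000    # Neandertal / Neandertal-related split
  tD12: 250000    # D1 / D2 split
  tDDR: 300000    # sampled Denisovan / introgressing Denisovan split
  tDN: 415000     # Neandertal / Denisovan ancestor split
  tADN: 590000    # unknown archaic / (N+D) ancestor split
  tAM: 655000     # modern / archaic root
  nBot: 250       # out-of-Africa founder (bottleneck) size, diploids
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
  tdYG2:   {dist: uniform, low: 50000, high: 145000}
  tdOA1:   {dist: uniform, low: 45000, high: 125000}
  tOAbot1: {dist: uniform, low: 40000, high: 125000}
  tdOA2:   {dist: uniform, low: 40000, high: 65000}
  tOAbot2: {dist: uniform, low: 35000, high: 65000}
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
  m1G2EA: {dist: uniform, low: 0.0, high: 0.001}
  m1EAG2: {dist: uniform, low: 0.0, high: 0.001}
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
  EA: max(nE, nA)
growth:
  - {population: P, rate: rP, modern_size: nP, bottleneck_time: tOAbot1, founder_size: nBot}
  - {population: EA, rate: rEA, modern_size: "max(nE, nA)", bottleneck_time: tOAbot2, founder_size: nBot}
events:
  # modern structure (backward in time)
  - {type: divergence, time: tdEA, derived: [E, A], ancestral: EA}
  - {type: divergence, time: tdOA2, derived: [EA], ancestral: G2, label: out_of_africa}
  - {type: divergence, time: tdG2BE, derived: [BE], ancestral: G2}
  - {type: divergence, time: tdOA1, derived: [P], ancestral: G1, label: out_of_africa}
  - {type: divergence, time: tdYG2, derived: [G2], ancestral: Y}
  - {type: divergence, time: tdYG1, derived: [Y, G1], ancestral: YG}
  # archaic scaffold
  - {type: divergence, time: tNNR, derived: [N, NR], ancestral: NNR}
  - {type: divergence, time: tD12, derived: [D1, D2], ancestral: D12}
  - {type: divergence, time: tDDR, derived: [D, D12], ancestral: DDR}
  - {type: divergence, time: tDN, derived: [NNR, DDR], ancestral: DN}
  - {type: divergence, time: tADN, derived: [AR, DN], ancestral: ADN}
  - {type: divergence, time: tAM, derived: [YG, ADN], ancestral: AM}
  # admixture pulses (forward-time source -> dest)
  - {type: pulse, time: taNG2, source: NR, dest: G2, proportion: paNG2}
  - {type: pulse, time: taNEA, source: NR, dest: EA, proportion: paNEA}
  - {type: pulse, time: taARP, source: AR, dest: P, proportion: paARP}
  - {type: pulse, time: taD1P, source: D1, dest: P, proportion: paD1P}
  - {type: pulse, time: taD2A, source: D2, dest: A, proportion: paD2A}
  - {type: pulse, time: taBEE, source: BE, dest: E, proportion: paBEE}
  # continuous migration windows (forward-time donor -> recipient)
  - {type: migration, rate: mYG1, source: Y, dest: G1, start: 0, end: tdYG1}
  - {type: migration, rate: mG1Y, source: G1, dest: Y, start: 0, end: tdYG1}
  - {type: migration, rate: mG1G2, source: G1, dest: G2, start: 0, end: tdYG2}
  - {type: migration, rate: mG2G1, source: G2, dest: G1, start: 0, end: tdYG2}
  - {type: migration, rate: mG2E, source: G2, dest: E, start: 0, end: tdEA}
  - {type: migration, rate: mEG2, source: E, dest: G2, start: 0, end: tdEA}
  - {type: migration, rate: mEA, source: E, dest: A, start: 0, end: tdEA}
  - {type: migration, rate: mAE, source: A, dest: E, start: 0, end: tdEA}
  - {type: migration, rate: mAP, source: A, dest: P, start: 0, end: tdEA}
  - {type: migration, rate: mPA, source: P, dest: A, start: 0, end: tdEA}
  # ancient window between the Eurasian split and the second exit
  - {type: migration, rate: m1G2EA, source: G2, dest: EA, start: tdEA, end: tdOA2}
  - {type: migration, rate: m1EAG2, source: EA, dest: G2, start: tdEA, end: tdOA2}
  - {type: migration, rate: m1EAP, source: EA, dest: P, start: tdEA, end: tdOA2}
  - {type: migration, rate: m1PEA, source: P, dest: EA, start: tdEA, end: tdOA2}
constraints:
  - tdOA1 < tdYG1
  - tOAbot1 < tdOA1
  - tdYG2 < tdYG1
  - tdOA2 < tdYG2
  - tdOA2 < tdOA1
  - tOAbot2 < tdOA2
  - tdEA < tOAbot2
  - tdG2BE < tdYG2
  - tdOA2 < taNG2
  - taNG2 < tdYG2
  - tdEA < taNEA
  - taNEA < tdOA2
  - taARP < tdOA1
  - taD1P < tdOA1
  - taD2A < tdEA
  - taBEE < tdEA
  - taBEE < tdG2BE
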