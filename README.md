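# vibmatch

Vibrational frequency scaling factors and quantitative spectral
matching for conformer identification.

## The problem

Calculated harmonic vibrational frequencies ω systematically
overestimate the fundamentals ν observed in measured spectra, because
the harmonic approximation neglects anharmonicity. Assigning a measured
spectrum to one of several candidate conformer structures therefore
takes two steps, both implemented here:

1. **Scaling** — derive multiplicative factors λ that map ω onto ν,
   by least squares over a database of paired frequencies:

   λ = Σ νᵢωᵢ / Σ ωᵢ², minimizing Σ (λωᵢ − νᵢ)².

   Factors can be *global* (one value), *range-dependent* (high
   >2000 cm⁻¹ / mid 1000–2000 cm⁻¹ / low <1000 cm⁻¹) or
   *mode-dependent* (the high range split into O–H, N–H, aromatic C–H
   and ethyl C–H stretches). A full error battery (RMS, mean absolute
   deviation, σ, MAPE, quartiles of |λω − ν|), repeated 70%/30%
   train/test resampling, and a top-20%-intensity stability check
   quantify how trustworthy each scheme is.

2. **Matching** — score a measured peak list against each scaled
   candidate spectrum with four methods: whole-spectrum
   cross-correlation (after Lorentzian convolution), average Euclidean
   and Manhattan *barcode* distances (minimal-cost Kuhn–Munkres
   assignment of measured to calculated features on frequency and
   weighted intensity), and the 1-D optimal-transport (Wasserstein-1)
   distance between intensity distributions. Candidates are ranked per
   method; rank 1 is the proposed structure.

The intended users are gas-phase/jet-cooled vibrational spectroscopists
comparing measured fundamental bands (e.g. ionization-detected
stimulated Raman peak lists) with DFT harmonic spectra of candidate
conformers. Eight functional/basis combinations are supported:
M06-2X(-D3), B3LYP(-D3) and wB97X-D with 6-311++G(d,p) and/or cc-pVTZ.

## Worked example

Simulate an identification problem (8 similar conformers, one of which
generated the "measured" spectrum under realistic noise), fit
mode-dependent scaling factors from a synthetic 824-row database, and
rank the candidates:

```
$ vibmatch simulate --seed 17 --out-dir scenario
wrote 8 candidates + measured spectrum to scenario (generating conformer: conf3)

$ python -c "
from vibmatch.io import write_pair_database
from vibmatch.records import TheoryLevel
from vibmatch.synthetic import make_pair_database
level = TheoryLevel('M06-2X-D3', '6-311++G(d,p)')
write_pair_database(make_pair_database(levels=[level], seed=17), [level], 'db.csv')"

$ vibmatch fit-scaling db.csv --scheme mode_dependent --out factors.json
CH_ethyl   lambda = 0.9496 +- 0.0016  (n = 112)
CH_ring    lambda = 0.9530 +- 0.0015  (n = 118)
NH         lambda = 0.9451 +- 0.0014  (n = 56)
OH         lambda = 0.9403 +- 0.0016  (n = 35)
low        lambda = 0.9727 +- 0.0086  (n = 182)
mid        lambda = 0.9737 +- 0.0037  (n = 321)

$ vibmatch match scenario/measured.csv scenario/candidate_*.csv \
      --factors factors.json --out ranks.csv
best by xcorr        : conf3
best by avg_euclid   : conf3
best by avg_manhattan: conf3
best by ot_dist      : conf0
```

Reading the output: each fitted λ is the per-class harmonic→fundamental
correction (a C–H stretch calculated at 3100 cm⁻¹ is predicted near
0.9496 × 3100 ≈ 2944 cm⁻¹), with Δλ the spread of per-pair ratios and
n the pairs behind it. In the match report, the barcode distances and
cross-correlation all point to `conf3` — the true generating conformer —
while optimal transport picks a wrong candidate, illustrating why
transport distance is kept as a cross-check rather than an
identification criterion. `ranks.csv` holds all four scores and ranks
per candidate.

The same operations are available as a library
(`vibmatch.fit_scaling_set`, `vibmatch.rank_candidates`, ...); see
`docs/methods.md` for the model, conventions and limitations.

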