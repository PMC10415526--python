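# betasw

Beta-band lagged-coherence connectivity and small-world network analysis
for resting-state EEG, with a synthetic sensorimotor cohort generator.

## The problem

In studies of post-stroke fatigue, resting-state EEG is used to ask whether
the functional organization of sensorimotor cortex differs between
high- and low-fatigue stroke survivors.  The analysis chain is long:
continuous 64-channel EEG is cleaned and epoched; current-density time
series for 26 Brodmann-area ROIs (13 areas × 2 hemispheres) are reduced to
weighted connectivity matrices for four networks — motor (BA 4, 6, 8, 9,
24, 32) and sensory (BA 1, 2, 3, 5, 7, 40, 43) in each hemisphere; each
matrix is summarized by a surrogate-normalized small-world index; and the
indices are compared between groups with a mixed-design ANOVA.  `betasw`
implements this chain as a tested, seeded, reusable library with a thin
CLI, plus a synthetic-cohort generator so every stage is testable without
access to clinical recordings.

## The model

**Connectivity.**  For ROI pair (i, j) with epoch-averaged cross-spectrum
S_ij(f) (Hann-tapered 2-s epochs, 0.5 Hz resolution), the lagged linear
coherence is

    LagR(f) = Im(S_ij)² / (S_ii S_jj − Re(S_ij)²),

averaged over the beta band (13–30 Hz).  Only the lagged (imaginary) part
of the cross-spectrum enters the numerator, so instantaneous mixing —
volume conduction, shared-source leakage — produces no spurious
connectivity.

**Graph metrics.**  For a weighted matrix W: C_brain is the mean Onnela
clustering coefficient (geometric-mean triangle intensity on
max-normalized weights) and L_brain the characteristic path length with
edge lengths 1/w.  Both are normalized by the means of 100 surrogate
random networks preserving node count, binary degree sequence, and the
edge-weight multiset:

    Cw = C_brain / C_random,   Lw = L_brain / L_random,   Sw = Cw / Lw.

Sw ≈ 1 marks a random-like network; Sw > 1 marks strong local clustering
combined with short global paths ("small-world properties").

**Group statistics.**  Fatigue group is defined by FSS-7 > 4.  After 3×IQR
extreme-outlier exclusion and Shapiro–Wilk/Levene checks, Sw enters a
three-way mixed ANOVA (fatigue × sex between subjects; network ×
hemisphere within), with Bonferroni-adjusted post-hoc t-tests and
nonparametric demographics tests (Spearman, Wilcoxon rank-sum,
Kruskal–Wallis).

## Worked example

```python
from betasw import (assemble_networks, default_coupling_spec,
                    generate_roi_timeseries, small_worldness)

spec = default_coupling_spec("high")   # sensory-network coupling hubs
roi = generate_roi_timeseries(spec, duration_s=60.0, rate_hz=250.0, seed=3)
for cm in assemble_networks(roi):
    m = small_worldness(cm.W, n_surrogates=100, seed=7)
    print(f"{cm.network:8s}{cm.hemisphere:6s} Cw={m.Cw:5.2f} "
          f"Lw={m.Lw:5.2f} Sw={m.Sw:5.2f}")
```

prints

```
motor    left   Cw= 0.98 Lw= 0.97 Sw= 1.01
motor    right  Cw= 0.98 Lw= 0.94 Sw= 1.04
sensory  left   Cw= 1.04 Lw= 0.82 Sw= 1.26
sensory  right  Cw= 1.04 Lw= 0.84 Sw= 1.23
```

The motor networks, with only baseline coupling, sit at Sw ≈ 1 (their own
surrogate null); the sensory networks, which carry the planted coupling
hub, are clearly small-world (Sw ≈ 1.25).  `examples/` contains one short
script per capability: cohort simulation, connectivity + small-worldness,
scalp preprocessing with artifact injection, and the end-to-end group
analysis (whose mixed-ANOVA table shows the planted network × fatigue
crossover: sensory Sw up, motor Sw down in high fatigue).

The same stages are available from the shell:

```bash
betasw simulate --seed 1 --out sim/
betasw connectivity --roi sim/S01.tsv --out conn/
betasw graph --matrices conn/ --surrogates 100 --seed 1 --out metrics.csv
betasw stats --metrics metrics.csv --subjects sim/subjects.csv --out stats/
betasw run --seed 7 --out run/        # everything, with a manifest
```

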