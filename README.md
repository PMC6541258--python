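# lurefx

Attractants (edible bait and scent lures) are widely used at camera-trap
stations to raise detection rates of elusive, small-bodied species — but they
can also change behaviour around the station, inflating detection while the
bait is fresh for some species and suppressing it for others. `lurefx`
implements a complete, tested analysis pipeline for quantifying those effects
from three tabular inputs: a capture log (species, station, timestamp), a
station deployment log, and an attractant refresh log. It is aimed at camera-
trap ecologists who bait their stations and need to know how detection
probability depends on attractant freshness and survey effort before drawing
community-level conclusions.

## What it computes

**Event processing.** Photo events are reduced to *independent captures*
(≥ 1 h since the previous retained capture of the same species at the same
station), each annotated with the time elapsed since the attractant at its
station was last refreshed.

**Occupancy-detection models.** Daily detection histories y_ij (stations ×
occasions, missing where a camera was inactive) are fitted with the standard
single-season occupancy likelihood

    L_i = ψ · Π_j p_ij^y_ij (1 − p_ij)^(1 − y_ij) + (1 − ψ) · 1{all y_ij = 0}

with constant occupancy, logit(ψ) = β_ψ, and detection modelled on
observation-level covariates, logit(p_ij) = β₀ + Σ_t β_t x_tij, where x is
attractant age (days since refresh), total effort (trap-days per station), or
incremental effort (active days accrued through occasion j). The six-model
set {null; each covariate; attractant + each effort} is ranked by
AICc = −2ℓ + 2K + 2K(K+1)/(n−K−1) with n = number of stations, and detection
curves with delta-method 95% CIs are exported.

**Short-term visitation response.** Independent captures are binned by 24-h
period since refresh (day 1: 0–24 h, …, day 7: 144–168 h) and the observed
per-bin proportions are compared with 1000 random capture histories of the
same size, each draw being (uniform captured station, uniform active date,
time of day from the species' fitted von Mises kernel activity density). The
rank p-value p = (#{null < obs} + ½·ties + 1)/(N + 1) classifies each bin as
*decreased* (p < 0.025), *increased* (p > 0.975), or no response.

**Synthetic surveys.** `lurefx.synthetic_data` generates complete surveys
(captures, deployments, refresh logs, truth JSON) with known ψ, β₀,
attractant effects, and diel activity mixtures, so every stage is testable
without field data.

## Worked example

```bash
python analysis/01_simulate.py          # 45 stations, 5-species guild
python analysis/02_descriptive_summaries.py
python analysis/03_occupancy_models.py
python analysis/04_permutation_test.py
python analysis/05_assemble_run.py      # manifest with content digests
```

On the default seed the simulated survey yields 1431 captures over 3270
trap-days, and the pipeline prints, per species, the best model by AICc and
the day bins with a significant visitation response:

```
civet: best psi(.) p(attractant_age) (AICc 590.0; significant: attractant_age)
golden_cat: best psi(.) p(.) (significant: none)
civet (80 captures): day 1: increased
duiker (326 captures): day 1: decreased; day 5: decreased
genet (264 captures): day 1: increased; day 3: increased
golden_cat (132 captures): no short-term response
```

The generator gave the civet and genet negative attractant-age effects
(detection highest at fresh bait), the duiker a positive one (avoids fresh
bait), and the golden cat none — the fitted model ranking and the day-1
classifications recover exactly that structure. `results/table1.csv` holds
the descriptive summary (independent captures, capture rate per 100
trap-days, naive detection/occupancy); `results/permutation_<species>.csv`
and `results/null_draws_<species>.csv` hold the test tables and the null
draws for violin plots.

The same pipeline runs on real CSV logs via the CLI:

```bash
lurefx run --captures caps.csv --deployments dep.csv --refresh ref.csv --out out/
lurefx simulate --seed 1 --out sim/
```

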