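# burstfish

Transcriptional-burst inference from single-molecule FISH (smFISH) data with
the two-state telegraph promoter model, together with the smFISH
intensity-to-count calibration it depends on and the relative-shift statistic
for sequencing-quantified nucleosome binding assays (EMSA-seq).

The package is aimed at quantitative biologists analyzing smFISH experiments
in which a gene's expression is compared between genotypes — for example a
wild-type embryo versus a transcription-factor mutant — and the question is
*which* kinetic step changed: how often the promoter turns on, or how much it
makes per burst.

## The model

A promoter switches between OFF and ON states at rates `k_on` and `k_off`;
while ON, transcripts are produced at rate `k_prod`; each mRNA degrades at
rate `delta`. With all rates expressed relative to `delta`, the stationary
copy-number distribution is the Poisson-Beta mixture

    p(N) = ∫₀¹ Pois(N; k_prod·x) · Beta(x; k_on, k_off) dx ,

equivalently the confluent-hypergeometric form of Peccoud & Ycart. Derived
quantities:

    burst frequency = k_on·k_off/(k_on + k_off)
    burst size      = k_prod/k_off
    mean expression = burst frequency × burst size = k_prod·k_on/(k_on + k_off)

A three-parameter fit to a count histogram alone is poorly identified, so the
fit exploits an extra observable: the fraction of cells showing a bright
nascent transcription site. Such cells are transcriptionally active, hence

    (nascent cells)/(empty cells) = active/inactive = k_on/k_off

is fixed during fitting, leaving (`k_on`, `k_prod`) free. Fitting minimizes
the unweighted sum of squared differences between observed histogram
frequencies and model bin probabilities (bounded trust-region search with
multi-starts); uncertainties come from a parametric bootstrap that resamples
synthetic datasets from the fitted law and refits them.

Per-cell transcript counts come from fluorescence: the total integrated
intensity of a cell divided by the mean integrated intensity of single
transcripts, each fitted as a 2D Gaussian (`integrated = 2π·A·σx·σy`).

For the nucleosome binding assay, templates carrying a binding motif at
defined superhelix positions of the Widom-601 scaffold are compared with the
motif-free 601 control: with per-band sequencing read counts,

    relative shift = −log2( (reads_N / reads_601) / (reads_input_N / reads_input_601) ) ,

a ratio-of-ratios that cancels depth, gel-excision and PCR biases.

## Worked example

Burst metrics and genotype fold changes from fitted parameter sets
(wild-type `k_on=2.7, k_off=3.7, k_prod=1524`; mutant
`k_on=0.19, k_off=5.1, k_prod=571`, all per mRNA lifetime):

```python
from burstfish import (KineticParams, NascentTally, active_inactive_ratio,
                       burst_metrics, compare_fits)

wt = KineticParams(k_on=2.7, k_off=3.7, k_prod=1524)
mut = KineticParams(k_on=0.19, k_off=5.1, k_prod=571)

print("wild-type active/inactive ratio:",
      round(active_inactive_ratio(NascentTally(n_nascent=41, n_empty=59)), 2))
m = burst_metrics(wt)
print(f"wild-type burst frequency {m.burst_frequency:.2f}/lifetime, "
      f"burst size {m.burst_size:.0f} transcripts")
fc = compare_fits(wt, mut, labels=("wild_type", "mutant"))
print(f"burst-frequency fold {fc.burst_frequency.fold:.1f} ({fc.burst_frequency.direction})")
print(f"burst-size fold      {fc.burst_size.fold:.1f} ({fc.burst_size.direction})")
```

prints

```
wild-type active/inactive ratio: 0.69
wild-type burst frequency 1.56/lifetime, burst size 412 transcripts
burst-frequency fold 8.5 (reduction)
burst-size fold      3.7 (reduction)
```

— in a wild-type cell the gene fires about 1.6 productive bursts per mRNA
lifetime of ~400 transcripts each; in the mutant, bursts are 8.5-fold rarer
and 3.7-fold smaller, so the dominant lesion is the activation step.

End-to-end on synthetic data with known ground truth (simulate per-cell
intensities → gate crystal cells on the marker channel → tally nascent
sites → constrained fit → bootstrap errors → fold changes):

```python
from burstfish import RunConfig, Scenario, run_burst_pipeline

config = RunConfig(
    seed=1,
    scenario=Scenario(seed=1, n_cells={"wild_type": 2000, "mutant": 2000}),
    reference="wild_type",
    n_reps=20,
)
report = run_burst_pipeline(config)
for genotype, entry in report["genotypes"].items():
    p = entry["params"]
    print(f"{genotype:10s} k_on={p['k_on']:.2f}+-{entry['se_k_on']:.2f} "
          f"k_prod={p['k_prod']:.0f}+-{entry['se_k_prod']:.0f} "
          f"reduced chi2={entry['gof']['reduced']:.2f}")
fold = report["fold_changes"]["mutant"]["burst_frequency"]
print(f"burst-frequency fold (planted 8.5): {fold['fold']:.2f} ({fold['direction']})")
```

prints

```
mutant     k_on=0.18+-0.01 k_prod=565+-101 reduced chi2=0.95
wild_type  k_on=2.36+-0.09 k_prod=1513+-54 reduced chi2=4.89
burst-frequency fold (planted 8.5): 7.69 (reduction)
```

The planted 8.5-fold burst-frequency reduction is recovered within 10%. The
wild-type reduced chi-square sits above 1 because the simulated intensities
carry 15% multiplicative measurement noise that the pure count model does
not describe — the same effect real calibration noise has.

A `burstfish` command-line tool exposes the same pipelines
(`simulate`, `quantify`, `fit`, `compare`, `nucshift`, `simulate-bands`,
`pmf`); run `burstfish --help`.

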