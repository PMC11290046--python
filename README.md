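# gp4pg

Evolutionary search over structured demographic models, scored against
genomic data through the fourfold joint site frequency spectrum.

## The problem

Choosing among competing demographic histories — who split from whom,
when, at what sizes, with how much gene flow — is usually done by
fitting a handful of hand-specified models.  This package instead
*evolves* a population of candidate models.  Each candidate is a rooted
tree of **ecodemes** (population units, internally structured into
stepping-stone chains of **topodemes**) whose divergences are **soft
splits**: after a split at time *T*, migration between the daughters
decays exponentially,

    m(t) = m_min + (m_max − m_min) · exp(−λ(T − t)/E),

rather than stopping outright.  Candidates are scored by coalescent
simulation (msprime): the simulation's **fourfold joint SFS** — the
joint spectrum of derived-allele counts on 2 chromosomes per population,
taken over every combination of 4 populations, (3⁴−2)·C(n,4) cells —
is compared to the observed spectrum by a standardized squared error

    f = Σ_s ((SS_sim − SS_obs)/σ_obs)²,

with per-cell σ from a block bootstrap over genomic fragments.  An
invasive-weed reproduction rule lets good models leave 8 mutated
offspring and bad ones 2, pools parents with children, and truncates —
so the best error never increases.  Mutation perturbs event times
(within their partial-order brackets), sizes, and migration parameters,
and can add or remove events, but never rewrites the split topology:
topologies compete through mixed starting populations and replicated
runs, and a PCA-based goodness-of-fit test checks whether the observed
data sits inside the cloud of spectra the fitted model generates.

The package also ships the observed-data side: VCF quality filters
(depth ≥ 5, QUAL ≥ 20, PASS, ±6 bp indel flanks, biallelic only),
neutrality masks (repeats/CNV/CpG, genes ±20 kb), 90%-density callable
windows (10 kb / 2.5 kb sliding), ancestral-allele polarization, and
blocking for the bootstrap — plus a synthetic-data factory used by the
test suite, so everything runs without external data.

## A worked example

Evolve a 4-population model against synthetic "observed" data:

```python
from gp4pg import (EngineConfig, basic_scenario, make_observed, run)
from gp4pg.sfs_stats import normalize_with_sigma
from gp4pg.simulate import GenomeSpec

sc = basic_scenario(n_pops=4, seed=5, genome=GenomeSpec(20, 10_000), n_base=2)
obs, sigma, truth = make_observed(sc, n_boot=200)
obs, sigma = normalize_with_sigma(obs, sigma)

cfg = EngineConfig(population_size=10, iterations=20, genome=sc.genome)
res = run(sc.competitors, cfg, obs, sigma, seed=21)
print(f"best error {res.best.fitness:.2f} after {res.iterations_run} iterations")
print(f"selected topology: {res.selected_topology}")
print("best-error trace:", [round(x, 1) for x in res.best_trace[:5]], "...")
```

prints

```
best error 86.49 after 20 iterations
selected topology: T0+mig
best-error trace: [176.9, 163.2, 125.9, 125.9, 93.1] ...
```

The error is the standardized squared deviation between the candidate's
simulated spectrum and the observed one (lower is better; it can only
fall across iterations because selection is elitist).  `T0+mig` names
the winning topology fixture — here the same split order that generated
the data.  The same flow is available from the shell:

```bash
gp4pg fixtures --n-pops 4 --seed 2 --out fix/
gp4pg run --observed fix/4jsfs.tsv --topologies fix/topologies \
          --seed 5 --out run/
gp4pg sfs --vcf cohort.vcf.gz --pops pops.tsv --masks masks/ \
          --anc ancestral.fa --out obs/   # observed-data pipeline
```

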