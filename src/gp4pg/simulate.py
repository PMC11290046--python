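"""Coalescent simulation of a demographic model into a per-site count table.

The model's epoch schedule (piecewise-constant migration matrices, Ne
vectors and deme sets) is translated into an msprime ``Demography``:
one haploid-sample population per (ecodeme, topodeme slot), migration
rate changes at every epoch boundary, mass migrations for splits and
topodeme-count reductions, and lineage movements for admixture pulses.
Genomic blocks are simulated as independent replicates (free
recombination between blocks) and mutations dropped under an
infinite-sites binary model, so every site is biallelic and polarized
by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import msprime
import numpy as np
import pandas as pd

from .demography import (
    DemographicModel,
    SoftSplit,
    AdmixturePulse,
    DemeCountChange,
    NeChange,
    epoch_schedule,
    validate_model,
)


@dataclass(frozen=True)
class GenomeSpec:
    """Blockwise genome: ``n_blocks`` independent fragments of fixed length."""

    n_blocks: int = 100
    block_length: int = 20_000
    recombination: float = 0.0

    def __post_init__(self):
        if self.n_blocks < 1 or self.block_length < 1:
            raise ValueError("n_blocks and block_length must be >= 1")

    @property
    def total_length(self) -> int:
        return self.n_blocks * self.block_length


@dataclass
class SimResult:
    """Site table of derived-allele counts per sampled ecodeme.

    ``sites`` has columns ``block``, ``pos`` and one integer column per
    sampled population (in ``populations`` order) holding the derived
    count among that population's sampled chromosomes.
    """

    sites: pd.DataFrame
    populations: list[str]
    n_chromosomes: dict[str, int]
    total_length: int


def _pop_name(eco: str, i: int) -> str:
    return f"{eco}__{i}"


def build_demography(model: DemographicModel) -> msprime.Demography:
    """Translate the model into an msprime Demography via its epoch schedule."""
    errors = validate_model(model)
    if errors:
        raise ValueError("invalid model: " + "; ".join(errors))

    demog = msprime.Demography()
    slots: list[tuple[str, int]] = []
    for eco in sorted(model.ecodemes, key=lambda e: e.position):
        for i in range(model.max_topodemes(eco.name)):
            slots.append((eco.name, i))
            demog.add_population(
                name=_pop_name(eco.name, i),
                initial_size=model.ne_at(eco.name, 0.0),
            )
    index = {lab: i for i, lab in enumerate(slots)}
    n = len(slots)

    epochs = epoch_schedule(model)

    def global_matrix(ep):
        mat = np.zeros((n, n))
        ids = [index[lab] for lab in ep.demes]
        sub = ep.migration
        for a, ga in enumerate(ids):
            for b, gb in enumerate(ids):
                mat[ga, gb] = sub[a, b]
        return mat

    current = global_matrix(epochs[0])
    demog.migration_matrix = current.copy()
    for ep in epochs[1:]:
        mat = global_matrix(ep)
        changed = np.argwhere(mat != current)
        for a, b in changed:
            if a == b:
                continue
            demog.add_migration_rate_change(
                time=ep.start,
                rate=mat[a, b],
                source=_pop_name(*slots[a]),
                dest=_pop_name(*slots[b]),
            )
        current = mat

    for ev in model.events:
        if isinstance(ev, NeChange):
            for i in range(model.max_topodemes(ev.ecodeme)):
                demog.add_population_parameters_change(
                    time=ev.time,
                    initial_size=ev.new_ne,
                    population=_pop_name(ev.ecodeme, i),
                )
        elif isinstance(ev, SoftSplit):
            parent_k = model.max_topodemes(ev.parent)
            for child in (ev.child_a, ev.child_b):
                for i in range(model.max_topodemes(child)):
                    demog.add_mass_migration(
                        time=ev.time,
                        source=_pop_name(child, i),
                        dest=_pop_name(ev.parent, min(i, parent_k - 1)),
                        proportion=1.0,
                    )
        elif isinstance(ev, DemeCountChange):
            # Backward in time past ev.time the ecodeme has ev.new_count
            # topodemes; lineages in slots beyond that collapse inward.
            top = model.max_topodemes(ev.ecodeme)
            if ev.new_count < top:
                for i in range(ev.new_count, top):
                    demog.add_mass_migration(
                        time=ev.time,
                        source=_pop_name(ev.ecodeme, i),
                        dest=_pop_name(ev.ecodeme, ev.new_count - 1),
                        proportion=1.0,
                    )
        elif isinstance(ev, AdmixturePulse):
            # Forward: fraction `proportion` of target ancestry arrives from
            # source; backward: target lineages jump to source.
            src_k = model.max_topodemes(ev.source)
            for i in range(model.max_topodemes(ev.target)):
                demog.add_mass_migration(
                    time=ev.time,
                    source=_pop_name(ev.target, i),
                    dest=_pop_name(ev.source, min(i, src_k - 1)),
                    proportion=ev.proportion,
                )
    demog.sort_events()
    return demog


def sampling_population(model: DemographicModel, eco: str) -> str:
    """Sampled topodeme of an ecodeme: the lattice-central one at present."""
    k = model.n_topodemes_at(eco, 0.0)
    return _pop_name(eco, (k - 1) // 2)


def simulate_dataset(
    model: DemographicModel, genome: GenomeSpec, seed: int
) -> SimResult:
    """Simulate polymorphism data under the model, reproducibly from ``seed``.

    Returns one site-table row per segregating (or sample-fixed derived)
    site, with derived counts tallied per sampled ecodeme.
    """
    pops = sorted(model.sampling, key=lambda nm: model.ecodeme(nm).position)
    if not pops:
        raise ValueError("model samples zero ecodemes")
    demog = build_demography(model)

    samples = [
        msprime.SampleSet(model.sampling[p], population=sampling_population(model, p), ploidy=1)
        for p in pops
    ]
    counts_per_pop = [model.sampling[p] for p in pops]
    col_slices = np.concatenate([[0], np.cumsum(counts_per_pop)])

    ss = np.random.SeedSequence(seed)
    anc_seed, mut_seed = (int(s.generate_state(1)[0] >> 1) + 1 for s in ss.spawn(2))

    reps = msprime.sim_ancestry(
        samples=samples,
        demography=demog,
        sequence_length=genome.block_length,
        recombination_rate=genome.recombination,
        num_replicates=genome.n_blocks,
        random_seed=anc_seed,
    )
    mut_rng = np.random.default_rng(mut_seed)
    rows = []
    counts_cols = [[] for _ in pops]
    blocks, positions = [], []
    for block_id, ts in enumerate(reps):
        mts = msprime.sim_mutations(
            ts,
            rate=model.mutation_rate,
            random_seed=int(mut_rng.integers(1, 2**31 - 1)),
            model=msprime.BinaryMutationModel(),
            discrete_genome=False,
        )
        if mts.num_sites == 0:
            continue
        gm = mts.genotype_matrix()  # sites x chromosomes, 0=ancestral
        derived = gm > 0
        for j in range(len(pops)):
            counts_cols[j].append(
                derived[:, col_slices[j] : col_slices[j + 1]].sum(axis=1)
            )
        blocks.append(np.full(mts.num_sites, block_id))
        positions.append(np.floor(mts.sites_position).astype(int) + 1)

    if blocks:
        data = {
            "block": np.concatenate(blocks),
            "pos": np.concatenate(positions),
        }
        for j, p in enumerate(pops):
            data[p] = np.concatenate(counts_cols[j]).astype(int)
        sites = pd.DataFrame(data)
    else:
        sites = pd.DataFrame(
            {"block": np.array([], int), "pos": np.array([], int)}
            | {p: np.array([], int) for p in pops}
        )
    return SimResult(
        sites=sites,
        populations=pops,
        n_chromosomes={p: model.sampling[p] for p in pops},
        total_length=genome.total_length,
    )


def sim_to_counts2(result: SimResult, seed: int | None = None) -> SimResult:
    """Reduce each population to derived counts on exactly 2 chromosomes.

    Populations sampled with more than 2 chromosomes are downsampled
    per site by drawing 2 chromosomes without replacement
    (hypergeometric); populations already at 2 pass through unchanged.
    """
    for p, k in result.n_chromosomes.items():
        if k < 2:
            raise ValueError(f"population {p} has fewer than 2 sampled chromosomes")
    if all(k == 2 for k in result.n_chromosomes.values()):
        return result
    rng = np.random.default_rng(seed)
    sites = result.sites.copy()
    for p in result.populations:
        k = result.n_chromosomes[p]
        if k > 2:
            sites[p] = rng.hypergeometric(sites[p].to_numpy(), k - sites[p].to_numpy(), 2)
    return SimResult(
        sites=sites,
        populations=result.populations,
        n_chromosomes={p: 2 for p in result.populations},
        total_length=result.total_length,
    )


def write_site_table(result: SimResult, path) -> None:
    result.sites.to_csv(path, sep="\t", index=False)


def write_vcf(result: SimResult, path, chrom_prefix: str = "block") -> None:
    """Emit the site table as a minimal VCF: one pseudo-diploid per population.

    Counts of 0/1/2 derived copies become genotypes 0/0, 0/1 and 1/1 on
    placeholder REF=A / ALT=G alleles, with the ancestral allele recorded
    in INFO/AA; blocks map to contigs.
    """
    if any(k != 2 for k in result.n_chromosomes.values()):
        raise ValueError("VCF export requires 2 chromosomes per population")
    gt = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for b in sorted(result.sites["block"].unique()):
            fh.write(f"##contig=<ID={chrom_prefix}{b}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(result.populations)
            + "\n"
        )
        for row in result.sites.itertuples(index=False):
            gts = "\t".join(gt[getattr(row, p)] for p in result.populations)
            fh.write(
                f"{chrom_prefix}{row.block}\t{row.pos}\t.\tA\tG\t50\tPASS\tAA=A\tGT\t{gts}\n"
            )


__all__ = [
    "GenomeSpec",
    "SimResult",
    "build_demography",
    "simulate_dataset",
    "sim_to_counts2",
    "write_site_table",
    "write_vcf",
]
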