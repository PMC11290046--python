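"""Synthetic-data factory: toy topologies, truth scenarios, toy VCF fixtures.

Everything here regenerates byte-identically from (spec, seed) and runs
without network access.  Topology fixtures re-express the study design —
a set of competing split orders over the same leaf populations, each in
a with-migration and a decay-only variant — at desk scale: a handful of
populations with 2 sampled chromosomes each, kilobase blocks, Ne in the
1e3–1e4 range and split times between 100 and 4000 generations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .demography import (
    DemographicModel,
    Ecodeme,
    MigrationDecayParams,
    SoftSplit,
    validate_model,
)
from .sfs_stats import (
    JointSFS4,
    SigmaVector,
    bootstrap_sigma,
    compute_summary,
    write_sfs,
)
from .simulate import GenomeSpec, sim_to_counts2, simulate_dataset

# toy-scale defaults
TOY_NE = 5000.0
TOY_SPLIT_YOUNGEST = 400.0
TOY_SPLIT_OLDEST = 4000.0
TOY_M_MAX = 5e-3
TOY_INTERNAL_MIGRATION = 1e-3
TOY_INTER_MIGRATION = 1e-4


@dataclass
class ScenarioSpec:
    truth: DemographicModel
    genome: GenomeSpec
    competitors: list[DemographicModel]
    seed: int = 0
    recovery_factor: float = 2.0

    def __post_init__(self):
        labels = {c.topology_label for c in self.competitors}
        if self.truth.topology_label not in labels:
            raise ValueError("truth topology must be among the competitors")


def _caterpillar_model(
    leaf_order: list[int],
    n_pops: int,
    label: str,
    scale: float,
    n_topodemes: int,
    with_migration: bool,
    ne: float = TOY_NE,
    m_max: float = TOY_M_MAX,
) -> DemographicModel:
    """Left caterpillar over a permuted leaf order.

    Leaves sit at lattice positions 0..n-1 scaled by 100; each ancestor
    takes a fresh position just right of its leftmost descendant leaf,
    which keeps the alive-set ordering consistent at all times.
    """
    leaves = [
        Ecodeme(f"P{i}", position=i * 100, n_topodemes=n_topodemes, ne_per_topodeme=ne)
        for i in range(n_pops)
    ]
    ecodemes = list(leaves)
    events = []
    times = np.geomspace(
        TOY_SPLIT_YOUNGEST * scale, TOY_SPLIT_OLDEST * scale, n_pops - 1
    )[::-1]
    # joins happen oldest-last: build forward joining list pairwise
    current = f"P{leaf_order[0]}"
    current_minpos = leaf_order[0] * 100
    offset = 1
    for j, nxt in enumerate(leaf_order[1:]):
        t = float(times[len(leaf_order) - 2 - j])
        parent = f"A{label}_{j}"
        minpos = min(current_minpos, nxt * 100)
        ecodemes.append(
            Ecodeme(parent, position=minpos + offset, n_topodemes=n_topodemes, ne_per_topodeme=ne)
        )
        offset += 1
        events.append(
            SoftSplit(
                parent=parent,
                child_a=current,
                child_b=f"P{nxt}",
                time=t,
                decay=MigrationDecayParams(
                    m_max=m_max, m_min=0.0, t_split=t, lambda_decay=1.0
                ),
            )
        )
        current = parent
        current_minpos = minpos
    variant = "+mig" if with_migration else "-mig"
    return DemographicModel(
        ecodemes=ecodemes,
        events=events,
        topology_label=f"{label}{variant}",
        sampling={f"P{i}": 2 for i in range(n_pops)},
        internal_migration=TOY_INTERNAL_MIGRATION if with_migration else 0.0,
        inter_ecodeme_migration=TOY_INTER_MIGRATION if with_migration else 0.0,
    )


def make_topology_fixtures(
    n_pops: int,
    scale: float = 1.0,
    n_base: int | None = None,
    n_topodemes: int = 1,
    variants: tuple[bool, ...] = (True, False),
    m_max: float = TOY_M_MAX,
) -> list[DemographicModel]:
    """Competing split-order topologies, each in ± topodeme-migration variants.

    Base topologies are caterpillar joins over rotated leaf orders, which
    gives distinct split identities per base.  With 6 bases and both
    variants this yields the 12-topology competition design; a single
    base gives 2 configs.
    """
    if not (3 <= n_pops <= 8):
        raise ValueError("n_pops must be in [3, 8]")
    if n_base is None:
        n_base = 6 if n_pops >= 6 else min(n_pops, 3)
    models = []
    for j in range(n_base):
        order = list(range(n_pops))
        order = order[j % n_pops :] + order[: j % n_pops]
        if j >= n_pops:  # more bases than rotations: reverse orders
            order = order[::-1]
        for with_migration in variants:
            m = _caterpillar_model(
                order, n_pops, f"T{j}", scale, n_topodemes, with_migration, m_max=m_max
            )
            violations = validate_model(m)
            if violations:  # pragma: no cover - construction guarantees validity
                raise AssertionError(f"fixture invalid: {violations}")
            models.append(m)
    return models


def make_observed(
    scenario: ScenarioSpec,
    out_dir: str | Path | None = None,
    n_boot: int = 1000,
) -> tuple[JointSFS4, SigmaVector, dict]:
    """Simulate the truth model into an observed summary + bootstrap sigma.

    Returns the counts-scale summary vector, its block-bootstrap sigma,
    and a truth sidecar (parameters of the generating model) for recovery
    assertions.  When ``out_dir`` is given, writes 4jsfs.tsv (with sigma
    column) and truth.json.
    """
    res = sim_to_counts2(
        simulate_dataset(scenario.truth, scenario.genome, scenario.seed),
        seed=scenario.seed,
    )
    obs = compute_summary(res.sites, res.populations)
    if len(res.sites) and res.sites["block"].nunique() >= 2:
        sigma = bootstrap_sigma(
            res.sites, res.populations, n_boot=n_boot, seed=scenario.seed, kind=obs.kind
        )
    else:
        sigma = SigmaVector(values=np.full(len(obs.values), 1.0))
    truth = {
        "topology_label": scenario.truth.topology_label,
        "split_times": {
            s.parent: s.time for s in scenario.truth.splits
        },
        "ne": {e.name: e.ne_per_topodeme for e in scenario.truth.ecodemes},
        "seed": scenario.seed,
        "genome": {
            "n_blocks": scenario.genome.n_blocks,
            "block_length": scenario.genome.block_length,
        },
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_sfs(obs, out / "4jsfs.tsv", sigma)
        (out / "truth.json").write_text(json.dumps(truth, indent=2))
    return obs, sigma, truth


def basic_scenario(
    n_pops: int = 4,
    seed: int = 1,
    genome: GenomeSpec | None = None,
    n_topodemes: int = 1,
    n_base: int = 2,
) -> ScenarioSpec:
    """A ready-made recovery scenario: truth = first topology fixture."""
    genome = genome or GenomeSpec(n_blocks=50, block_length=20_000)
    competitors = make_topology_fixtures(
        n_pops, n_base=n_base, n_topodemes=n_topodemes
    )
    return ScenarioSpec(
        truth=competitors[0].copy(), genome=genome, competitors=competitors, seed=seed
    )


RECOVERY_NE = 800.0
RECOVERY_SPLITS = (1500.0, 4500.0)
RECOVERY_TIME_CAP = 6000.0


def recovery_scenario(seed: int = 0, genome: GenomeSpec | None = None) -> ScenarioSpec:
    """The canonical 3-population split-time-recovery scenario.

    Truth is the first topology with hard splits (m_max = 0) at 1500 and
    4500 generations and Ne 800 per topodeme, against two competing split
    orders (both migration variants) whose times start at the fixture
    defaults.  Divergence times this deep relative to 2N leave a clean,
    unimodal footprint in the 3-state spectrum at ~0.8 Mb, which is what
    makes factor-2 recovery a meaningful check at desk scale; with only
    3 sampled populations the engine scores candidates on the full
    3-state spectrum.  Pair with :func:`recovery_engine_config`.
    """
    from dataclasses import replace

    genome = genome or GenomeSpec(n_blocks=40, block_length=20_000)
    competitors = make_topology_fixtures(3, n_base=2, n_topodemes=1, m_max=0.0)
    for c in competitors:
        c.ecodemes = [replace(e, ne_per_topodeme=RECOVERY_NE) for e in c.ecodemes]
    truth = competitors[0].copy()
    new_events = []
    for ev in truth.events:
        t_new = RECOVERY_SPLITS[0] if ev.time < 1000 else RECOVERY_SPLITS[1]
        new_events.append(
            replace(ev, time=t_new, decay=replace(ev.decay, t_split=t_new))
        )
    truth.events = new_events
    return ScenarioSpec(truth=truth, genome=genome, competitors=competitors, seed=seed)


def recovery_engine_config(genome: GenomeSpec | None = None):
    """Engine settings for the split-time-recovery study.

    The study asks whether the search recovers *times* under a known
    structure, so mutation is restricted to event times, with the search
    range bounded (the analogue of a bounded prior); sizes stay at their
    configured values.  Reduced scale: population 10, up to 30 iterations
    with plateau stopping after 10 without improvement.
    """
    from .engine import EngineConfig

    return EngineConfig(
        population_size=10,
        iterations=30,
        genome=genome or GenomeSpec(n_blocks=40, block_length=20_000),
        plateau_window=10,
        mutation_rates={
            "time": 0.9,
            "ne": 0.0,
            "admixture": 0.0,
            "migration": 0.0,
            "add_event": 0.0,
            "remove_event": 0.0,
            "time_cap": RECOVERY_TIME_CAP,
        },
    )


# ---- toy VCF / BED / ancestral-FASTA fixture --------------------------------


@dataclass
class ToyVcfSpec:
    """Layout of the hand-designed filtering fixture (1 contig)."""

    chrom: str = "chr1"
    chrom_length: int = 60_000
    samples: tuple[str, ...] = ("POP1", "POP2", "POP3", "POP4")


def make_toy_vcf(out_dir: str | Path, spec: ToyVcfSpec | None = None) -> dict:
    """Write a toy VCF + mask BEDs + ancestral FASTA with a known survivor set.

    Every filter class is represented: low depth, low QUAL, non-PASS,
    multiallelic, indel-flank proximity (with exact 6-bp boundary cases),
    repeat/CNV masks, a gene with its 20-kb flank boundary, a CpG island,
    and ancestral alleles matching REF, ALT and neither.  The sidecar
    JSON records the expected surviving positions and the reason each
    other record drops — the construction itself is the oracle.
    """
    spec = spec or ToyVcfSpec()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    C = spec.chrom

    # Region layout (0-based BED):
    #   repeat mask   [1000, 1200)
    #   CNV mask      [2000, 2500)
    #   gene          [40000, 42000) -> masked with 20 kb flank: [20000, 60000)
    #   CpG island    [3000, 3100)
    gene_start = 40_000
    masks = {
        "repeats.bed": [(1000, 1200)],
        "cnv.bed": [(2000, 2500)],
        "genes.bed": [(gene_start, 42_000)],
        "cpg.bed": [(3000, 3100)],
    }
    for name, ivals in masks.items():
        with open(out / name, "w") as fh:
            for a, b in ivals:
                fh.write(f"{C}\t{a}\t{b}\n")

    # records: (pos, ref, alts, qual, filter, DP, gts, expected)
    # genotypes as VCF GT strings for the 4 diploid samples
    het = ("0/1", "0/0", "0/0", "0/0")
    indel_pos = 5000  # REF=AT deletion; flank +-6 bp around [5000, 5001]
    records = [
        (300, "A", ["G"], 50, "PASS", 30, het, "keep"),
        (400, "A", ["G"], 50, "PASS", 3, het, "drop:depth"),
        (500, "A", ["G"], 10, "PASS", 30, het, "drop:qual"),
        (600, "A", ["G"], 50, "q10", 30, het, "drop:not_pass"),
        (700, "A", ["G", "T"], 50, "PASS", 30, het, "drop:multiallelic"),
        (indel_pos, "AT", ["A"], 50, "PASS", 30, het, "drop:indel_record"),
        (indel_pos - 6, "C", ["T"], 50, "PASS", 30, het, "drop:indel_flank"),
        (indel_pos - 7, "C", ["T"], 50, "PASS", 30, het, "keep"),
        (indel_pos + 7, "C", ["T"], 50, "PASS", 30, het, "drop:indel_flank"),
        (indel_pos + 8, "C", ["T"], 50, "PASS", 30, het, "keep"),
        (1100, "A", ["G"], 50, "PASS", 30, het, "drop:mask_repeats"),
        (2200, "A", ["G"], 50, "PASS", 30, het, "drop:mask_cnv"),
        (3050, "A", ["G"], 50, "PASS", 30, het, "drop:mask_cpg"),
        # gene flank boundary: gene starts at 1-based 40001, flank reaches
        # down to 1-based 20001 inclusive
        (20_000, "A", ["G"], 50, "PASS", 30, het, "keep"),
        (20_001, "A", ["G"], 50, "PASS", 30, het, "drop:mask_genes"),
        (41_000, "A", ["G"], 50, "PASS", 30, het, "drop:mask_genes"),
        # polarization cases
        (800, "A", ["G"], 50, "PASS", 30, ("1/1", "0/0", "0/0", "0/0"), "keep"),  # AA=G flip
        (900, "A", ["G"], 50, "PASS", 30, het, "drop:ancestral_mismatch"),  # AA=T
    ]
    aa = {800: "G", 900: "T"}
    anc = np.full(spec.chrom_length, "A", dtype="U1")
    for pos, ref, alts, *_ in records:
        anc[pos - 1] = aa.get(pos, ref[0])

    with open(out / "ancestral.fa", "w") as fh:
        fh.write(f">{C}\n")
        s = "".join(anc)
        for i in range(0, len(s), 60):
            fh.write(s[i : i + 60] + "\n")

    with open(out / "toy.vcf", "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={C},length={spec.chrom_length}>\n")
        fh.write('##FILTER=<ID=q10,Description="low quality">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(spec.samples)
            + "\n"
        )
        for pos, ref, alts, qual, filt, dp, gts, _exp in sorted(records):
            fh.write(
                f"{C}\t{pos}\t.\t{ref}\t{','.join(alts)}\t{qual}\t{filt}\t"
                f"DP={dp}\tGT\t" + "\t".join(gts) + "\n"
            )

    sidecar = {
        "chrom": C,
        "survivors": sorted(p for p, *rest in records if rest[-1] == "keep"),
        "expectations": {str(p): rec[-1] for p, *rec in records},
        "gene_flank_bp": 20_000,
        "indel_flank_bp": 6,
        "pops": {s: s for s in spec.samples},
    }
    (out / "sidecar.json").write_text(json.dumps(sidecar, indent=2))
    return sidecar


__all__ = [
    "ScenarioSpec",
    "ToyVcfSpec",
    "make_topology_fixtures",
    "make_observed",
    "basic_scenario",
    "make_toy_vcf",
]
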