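"""Fourfold joint SFS summary statistics and the standardized fitness.

Each population contributes a derived-allele count on exactly 2
chromosomes, i.e. 3 states (0/1/2).  For every combination of 4
populations the joint spectrum has 3^4 = 81 cells; the two cells that are
monomorphic across the whole quadruple (all-0 and all-2) are removed,
leaving 79.  Concatenating the 79-cell segments over all C(n,4)
quadruples (in lexicographic order of population indices) gives the
fourfold joint SFS (4jSFS) vector of length (3^4 - 2) * C(n,4) — a
drastic reduction versus the full multidimensional spectrum's 3^n - 2
while retaining the pairwise-and-beyond frequency information that
demographic parameters act on.

Fitness of a simulated dataset against the observed one is the summed
squared per-cell deviation standardized by the observed cells' block-
bootstrap standard errors.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

N_CELLS_4 = 3**4 - 2  # 79
_POWERS4 = np.array([27, 9, 3, 1])
SIGMA_EPSILON = 1.0


@dataclass(frozen=True)
class JointSFS4:
    """A concatenated joint-SFS summary vector.

    ``kind`` is ``"4jsfs"`` (79-cell segments over all population
    quadruples) or ``"msfs"`` (a single (3^n - 2)-cell segment, the
    full-spectrum fallback used when fewer than 4 populations are
    available).  ``normalization`` is ``"counts"`` or ``"proportions"``.
    """

    populations: tuple[str, ...]
    values: np.ndarray
    kind: str = "4jsfs"
    normalization: str = "counts"

    @property
    def n_populations(self) -> int:
        return len(self.populations)

    @property
    def segment_length(self) -> int:
        return N_CELLS_4 if self.kind == "4jsfs" else 3 ** self.n_populations - 2

    @property
    def n_segments(self) -> int:
        return len(self.values) // self.segment_length


@dataclass(frozen=True)
class SigmaVector:
    values: np.ndarray
    epsilon: float = SIGMA_EPSILON


@dataclass(frozen=True)
class FitnessValue:
    value: float


def expected_length(n: int) -> int:
    """4jSFS vector length for ``n`` populations: (3^4 - 2) * C(n, 4)."""
    from math import comb

    return N_CELLS_4 * comb(n, 4)


def classify_site(counts4) -> int | None:
    """Map 4 per-population counts in {0,1,2} to a 4jSFS cell index.

    The base-3 code c1*27 + c2*9 + c3*3 + c4 is indexed 0..78 after
    removing the quadruple-monomorphic codes 0 (all ancestral) and 80
    (all derived); those return ``None`` (excluded).
    """
    c = np.asarray(counts4, dtype=int)
    if c.shape != (4,) or c.min() < 0 or c.max() > 2:
        raise ValueError("counts must be 4 values in {0,1,2}")
    code = int(c @ _POWERS4)
    if code == 0 or code == 80:
        return None
    return code - 1


def _counts_matrix(sites, populations) -> np.ndarray:
    if isinstance(sites, pd.DataFrame):
        m = sites[list(populations)].to_numpy(dtype=int)
    else:
        m = np.asarray(sites, dtype=int)
    if m.size and (m.min() < 0 or m.max() > 2):
        raise ValueError("per-population counts must lie in {0,1,2}")
    return m


def compute_4jsfs(sites, populations) -> JointSFS4:
    """Tally the fourfold joint SFS over all population quadruples.

    ``sites`` is a (n_sites, n_pops) matrix of counts in {0,1,2} or a
    DataFrame with one column per population.  Sites monomorphic across a
    quadruple are excluded from that quadruple's segment only.
    """
    populations = tuple(populations)
    n = len(populations)
    if n < 4:
        raise ValueError("4jSFS requires at least 4 populations")
    m = _counts_matrix(sites, populations)
    segs = []
    for quad in itertools.combinations(range(n), 4):
        codes = m[:, quad] @ _POWERS4 if len(m) else np.array([], int)
        codes = codes[(codes != 0) & (codes != 80)]
        segs.append(np.bincount(codes - 1, minlength=N_CELLS_4).astype(float))
    return JointSFS4(populations=populations, values=np.concatenate(segs))


def compute_msfs(sites, populations) -> JointSFS4:
    """Full 3-state multidimensional SFS, length 3^n - 2 (fallback for n < 4)."""
    populations = tuple(populations)
    n = len(populations)
    m = _counts_matrix(sites, populations)
    powers = 3 ** np.arange(n - 1, -1, -1)
    top = 3**n - 1
    codes = m @ powers if len(m) else np.array([], int)
    codes = codes[(codes != 0) & (codes != top)]
    values = np.bincount(codes - 1, minlength=top - 1).astype(float)
    return JointSFS4(populations=populations, values=values, kind="msfs")


def compute_summary(sites, populations) -> JointSFS4:
    """4jSFS when >= 4 populations, full 3-state spectrum otherwise."""
    if len(tuple(populations)) >= 4:
        return compute_4jsfs(sites, populations)
    return compute_msfs(sites, populations)


def _per_block_matrix(sites: pd.DataFrame, populations, kind: str) -> np.ndarray:
    fn = compute_4jsfs if kind == "4jsfs" else compute_msfs
    blocks = sorted(sites["block"].unique())
    return np.stack(
        [fn(sites[sites["block"] == b], populations).values for b in blocks]
    )


def bootstrap_sigma(
    sites: pd.DataFrame,
    populations,
    n_boot: int = 1000,
    seed: int | None = None,
    epsilon: float = SIGMA_EPSILON,
    kind: str = "4jsfs",
) -> SigmaVector:
    """Block-bootstrap standard error of each summary cell.

    Genomic blocks (the ``block`` column) are resampled with replacement
    to the original block count ``n_boot`` times; the per-cell standard
    deviation of the recomputed summary vectors is the error estimate,
    floored at ``epsilon`` so downstream standardization never divides by
    zero.
    """
    blocks = sites["block"].unique()
    if len(blocks) < 2:
        raise ValueError("sigma undefined: need at least 2 blocks")
    per_block = _per_block_matrix(sites, populations, kind)
    rng = np.random.default_rng(seed)
    b = len(per_block)
    idx = rng.integers(0, b, size=(n_boot, b))
    reps = per_block[idx].sum(axis=1)
    sd = reps.std(axis=0, ddof=1)
    return SigmaVector(values=np.maximum(sd, epsilon), epsilon=epsilon)


def fitness(ss_sim: JointSFS4, ss_obs: JointSFS4, sigma: SigmaVector) -> FitnessValue:
    """Standardized squared error between simulated and observed summaries.

    f = sum_s ((SS_sim^s - SS_obs^s) / sigma_obs^s)^2; zero iff the two
    vectors agree on every cell.
    """
    if ss_sim.populations != ss_obs.populations:
        raise ValueError("population orders differ")
    if len(ss_sim.values) != len(ss_obs.values) or len(sigma.values) != len(
        ss_obs.values
    ):
        raise ValueError("summary/sigma lengths differ")
    if ss_sim.normalization != ss_obs.normalization:
        raise ValueError("normalizations differ")
    z = (ss_sim.values - ss_obs.values) / sigma.values
    return FitnessValue(float(np.dot(z, z)))


def normalize_sfs(jsfs: JointSFS4, mode: str = "per_quadruple") -> JointSFS4:
    """Convert a counts vector to proportions.

    ``per_quadruple`` scales each segment to sum to 1 (all-zero segments
    stay zero, with a warning); ``global`` scales the whole vector by its
    total.  Idempotent on already-normalized input.
    """
    if jsfs.normalization == "proportions":
        return jsfs
    values = jsfs.values.astype(float).copy()
    if mode == "per_quadruple":
        L = jsfs.segment_length
        for i in range(jsfs.n_segments):
            seg = values[i * L : (i + 1) * L]
            tot = seg.sum()
            if tot > 0:
                seg /= tot
            else:
                logger.warning("all-zero summary segment %d left unnormalized", i)
    elif mode == "global":
        tot = values.sum()
        if tot > 0:
            values /= tot
        else:
            logger.warning("all-zero summary vector left unnormalized")
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return replace(jsfs, values=values, normalization="proportions")


def normalize_with_sigma(
    jsfs: JointSFS4, sigma: SigmaVector, mode: str = "per_quadruple"
) -> tuple[JointSFS4, SigmaVector]:
    """Normalize a counts summary and rescale its sigma by the same factors."""
    if jsfs.normalization == "proportions":
        return jsfs, sigma
    values = sigma.values.astype(float).copy()
    eps = sigma.epsilon
    if mode == "per_quadruple":
        L = jsfs.segment_length
        scaled_eps = eps
        for i in range(jsfs.n_segments):
            tot = jsfs.values[i * L : (i + 1) * L].sum()
            if tot > 0:
                values[i * L : (i + 1) * L] /= tot
                scaled_eps = min(scaled_eps, eps / tot)
        values = np.maximum(values, min(scaled_eps, eps))
    else:
        tot = jsfs.values.sum()
        if tot > 0:
            values = np.maximum(values / tot, eps / tot)
    return normalize_sfs(jsfs, mode), SigmaVector(values=values, epsilon=sigma.epsilon)


# ---- persistence ------------------------------------------------------------


def _cell_labels(jsfs: JointSFS4) -> list[str]:
    labels = []
    if jsfs.kind == "4jsfs":
        quads = list(itertools.combinations(jsfs.populations, 4))
        for quad in quads:
            for code in range(1, 80):
                labels.append("|".join(quad) + f":{code}")
    else:
        top = 3 ** jsfs.n_populations - 1
        for code in range(1, top):
            labels.append("|".join(jsfs.populations) + f":{code}")
    return labels


def write_sfs(jsfs: JointSFS4, path, sigma: SigmaVector | None = None) -> None:
    """Persist a summary vector (and optionally its sigma) as TSV."""
    with open(path, "w") as fh:
        fh.write(f"# populations: {','.join(jsfs.populations)}\n")
        fh.write(f"# kind: {jsfs.kind}\n")
        fh.write(f"# normalization: {jsfs.normalization}\n")
        cols = "cell\tvalue" + ("\tsigma" if sigma is not None else "")
        fh.write(cols + "\n")
        for i, lab in enumerate(_cell_labels(jsfs)):
            row = f"{lab}\t{jsfs.values[i]:.10g}"
            if sigma is not None:
                row += f"\t{sigma.values[i]:.10g}"
            fh.write(row + "\n")


def read_sfs(path) -> tuple[JointSFS4, SigmaVector | None]:
    meta = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
            elif line.strip() and not line.startswith("cell\t"):
                rows.append(line.rstrip("\n").split("\t"))
    values = np.array([float(r[1]) for r in rows])
    jsfs = JointSFS4(
        populations=tuple(meta["populations"].split(",")),
        values=values,
        kind=meta.get("kind", "4jsfs"),
        normalization=meta.get("normalization", "counts"),
    )
    sigma = None
    if rows and len(rows[0]) > 2:
        sigma = SigmaVector(values=np.array([float(r[2]) for r in rows]))
    return jsfs, sigma


__all__ = [
    "N_CELLS_4",
    "SIGMA_EPSILON",
    "JointSFS4",
    "SigmaVector",
    "FitnessValue",
    "expected_length",
    "classify_site",
    "compute_4jsfs",
    "compute_msfs",
    "compute_summary",
    "bootstrap_sigma",
    "fitness",
    "normalize_sfs",
    "normalize_with_sigma",
    "write_sfs",
    "read_sfs",
]
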