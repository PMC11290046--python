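"""Goodness-of-fit and run diagnostics for fitted demographic models.

A fitted model is checked by simulating many replicate datasets under
it, embedding their summary vectors with principal components, and
asking whether the observed data falls inside the simulated cloud:
components are fitted on the simulations only, the observed point is
projected, and its Mahalanobis distance in the components covering >=
90% of variance is ranked against the simulated distances.  The model
is flagged a poor fit when the observed percentile exceeds 99.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.decomposition import PCA

from .demography import DemographicModel
from .engine import RunResult
from .sfs_stats import JointSFS4, compute_summary, normalize_sfs
from .simulate import GenomeSpec, sim_to_counts2, simulate_dataset

VARIANCE_RETAINED = 0.90
OUTLIER_PERCENTILE = 99.0


@dataclass
class GofResult:
    sim_coords: np.ndarray  # (n_sims, k)
    obs_coords: np.ndarray  # (n_obs_replicates, k)
    observed_score: float  # Mahalanobis distance of the mean observed point
    percentile: float  # of the observed score within the simulated cloud
    is_outlier: bool
    n_components: int
    threshold: float = OUTLIER_PERCENTILE

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "observed_score": self.observed_score,
                    "percentile": self.percentile,
                    "is_outlier": bool(self.is_outlier),
                    "n_components": self.n_components,
                    "threshold": self.threshold,
                },
                indent=2,
            )
        )


def simulate_summaries(
    model: DemographicModel,
    genome: GenomeSpec,
    populations,
    n_sims: int,
    seed: int,
    normalization: str = "proportions",
) -> np.ndarray:
    """Matrix of summary vectors from independent simulations of a model."""
    ss = np.random.SeedSequence(seed)
    rows = []
    for child in ss.spawn(n_sims):
        s = int(child.generate_state(1)[0] >> 1)
        res = sim_to_counts2(simulate_dataset(model, genome, s), seed=s)
        summary = compute_summary(res.sites, populations)
        if normalization == "proportions":
            summary = normalize_sfs(summary)
        rows.append(summary.values)
    return np.stack(rows)


def gof_pca(
    model: DemographicModel,
    observed_replicates: "np.ndarray | list[JointSFS4]",
    genome: GenomeSpec,
    seed: int,
    n_sims: int = 1000,
    variance_retained: float = VARIANCE_RETAINED,
    threshold: float = OUTLIER_PERCENTILE,
    populations=None,
    sim_matrix: np.ndarray | None = None,
    normalization: str = "counts",
) -> GofResult:
    """PCA goodness-of-fit of a model against observed replicate summaries.

    Principal components are fitted on the simulated summary matrix only
    (``n_sims`` simulations, or a precomputed ``sim_matrix``); the
    observed replicates are projected onto them.  The observed score is
    the Mahalanobis distance of the mean observed point in the retained
    components, and the percentile is its rank among the simulated
    distances.
    """
    if isinstance(observed_replicates, list):
        populations = observed_replicates[0].populations
        normalization = observed_replicates[0].normalization
        obs = np.stack([o.values for o in observed_replicates])
    else:
        obs = np.asarray(observed_replicates)
    if sim_matrix is None:
        if n_sims < 30:
            raise ValueError("need at least 30 simulations")
        if populations is None:
            raise ValueError("populations required to simulate the reference cloud")
        sim_matrix = simulate_summaries(
            model, genome, populations, n_sims, seed, normalization=normalization
        )
    if sim_matrix.std(axis=0).max() == 0:
        raise ValueError("degenerate simulation matrix: zero variance everywhere")

    n_comp = min(len(sim_matrix) - 1, sim_matrix.shape[1])
    pca = PCA(n_components=n_comp)
    sim_pc = pca.fit_transform(sim_matrix)
    ratios = pca.explained_variance_ratio_
    k = int(np.searchsorted(np.cumsum(ratios), variance_retained) + 1)
    k = min(max(k, 1), n_comp)

    evar = np.maximum(pca.explained_variance_[:k], np.finfo(float).tiny)

    # Squared score = Mahalanobis distance in the retained components plus
    # the reconstruction residual standardized by its simulated mean, so
    # deviations orthogonal to the retained subspace still register.
    def _score_parts(X):
        pc = pca.transform(X)
        recon = pc[:, :k] @ pca.components_[:k] + pca.mean_
        spe = ((X - recon) ** 2).sum(axis=1)
        return pc[:, :k], spe

    sim_k, sim_spe = _score_parts(sim_matrix)
    mean_spe = max(float(sim_spe.mean()), np.finfo(float).tiny)
    sim_d = np.sqrt(((sim_k**2) / evar).sum(axis=1) + sim_spe / mean_spe)

    obs_pc_full, _ = _score_parts(obs)
    obs_point = obs.mean(axis=0, keepdims=True)
    obs_k, obs_spe = _score_parts(obs_point)
    obs_d = float(np.sqrt(((obs_k[0] ** 2) / evar).sum() + obs_spe[0] / mean_spe))
    obs_pc = obs_pc_full
    percentile = 100.0 * float(np.mean(sim_d < obs_d))
    return GofResult(
        sim_coords=sim_pc[:, :k],
        obs_coords=obs_pc,
        observed_score=obs_d,
        percentile=percentile,
        is_outlier=percentile > threshold,
        n_components=k,
        threshold=threshold,
    )


def observed_replicates_by_bootstrap(
    sites, populations, n_replicates: int = 40, seed: int = 0, kind: str = "4jsfs",
    normalization: str = "counts",
) -> np.ndarray:
    """Block-bootstrap replicate summaries of one observed dataset."""
    from .sfs_stats import _per_block_matrix

    per_block = _per_block_matrix(sites, populations, kind)
    rng = np.random.default_rng(seed)
    b = len(per_block)
    idx = rng.integers(0, b, size=(n_replicates, b))
    reps = per_block[idx].sum(axis=1).astype(float)
    if normalization == "proportions":
        from .sfs_stats import N_CELLS_4

        L = N_CELLS_4 if kind == "4jsfs" else reps.shape[1]
        for i in range(reps.shape[1] // L):
            seg = reps[:, i * L : (i + 1) * L]
            tot = seg.sum(axis=1, keepdims=True)
            np.divide(seg, tot, out=seg, where=tot > 0)
    return reps


@dataclass
class TraceReport:
    final_errors: list[float]
    min_final_error: float
    max_final_error: float
    plateau_iterations: list[int]  # iteration of last improvement per run
    support: dict[str, int]


def trace_report(results: list[RunResult], tol: float = 0.0) -> TraceReport:
    """Summarize a set of runs: final errors, plateau onset, topology support."""
    if not results:
        raise ValueError("need at least one run")
    finals, plateaus = [], []
    support: dict[str, int] = {}
    for r in results:
        finals.append(r.best_trace[-1])
        last_improve = 0
        for i in range(1, len(r.best_trace)):
            if r.best_trace[i] < r.best_trace[i - 1] - tol:
                last_improve = i
        plateaus.append(last_improve)
        support[r.selected_topology] = support.get(r.selected_topology, 0) + 1
    return TraceReport(
        final_errors=finals,
        min_final_error=min(finals),
        max_final_error=max(finals),
        plateau_iterations=plateaus,
        support=support,
    )


def plot_gof(result: GofResult, path) -> None:
    """Optional scatter of the first two retained components."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    s = result.sim_coords
    o = result.obs_coords
    ax.scatter(s[:, 0], s[:, 1] if s.shape[1] > 1 else np.zeros(len(s)), s=8, alpha=0.4, label="simulated")
    ax.scatter(o[:, 0], o[:, 1] if o.shape[1] > 1 else np.zeros(len(o)), s=14, c="crimson", label="observed")
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


__all__ = [
    "GofResult",
    "TraceReport",
    "gof_pca",
    "simulate_summaries",
    "observed_replicates_by_bootstrap",
    "trace_report",
    "plot_gof",
]
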