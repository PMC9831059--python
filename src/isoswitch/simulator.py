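"""Ground-truthed simulator for time-course isoform expression data.

Generative model, per gene:

1. The number of isoforms ``k`` is Poisson-distributed (clamped to >= 1;
   single-isoform genes are kept as non-switching background).
2. A two-state (unswitched/switched) first-order Markov chain over the time
   points determines when the gene switches; the chain starts unswitched.
3. Isoform fractions come from one Dirichlet draw; the switched state reuses
   that draw with a designated isoform pair swapped.  Model 1 concentrates
   mass on ``n_switching`` isoforms (alpha = 10, 20, ..., rest 1) and swaps
   the two highest-alpha isoforms; Model 2 uses alpha = 10, 20, ..., 10*k and
   swaps a random pair among isoforms whose drawn fraction exceeds 0.3
   (falling back to the two largest).
4. Transcript means are fraction * gene mean; the per-transcript variance is
   Gamma-distributed (shape = mean + noise, scale = noise) so variance grows
   with both abundance and the noise level, and replicate values are Normal
   draws truncated at zero.

Every gene owns an independent RNG substream spawned from the master seed, so
changing ``n_genes`` does not reshuffle previously generated genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from isoswitch.core_data import TimeCourseMatrix, write_expression, write_gene_map

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "sample_state_paths",
    "sample_isoform_probabilities",
    "sample_counts",
    "simulate",
    "write_dataset",
    "load_truth",
]

DEFAULT_TRANSITIONS = np.array([[0.9, 0.1], [0.1, 0.9]])


@dataclass
class SimulationConfig:
    """Parameters of one simulation run.

    ``gene_mean_source`` may be a list of positive means (sampled uniformly
    with replacement, mimicking resampling from a reference dataset) or a
    ``(log_mean, log_sd)`` tuple of a log-normal distribution.  The default
    log-normal concentrates mass on well-expressed genes so that isoform
    fractions stay resolvable at the highest noise level.
    """

    n_genes: int = 1000
    n_timepoints: int = 10
    n_replicates: int = 3
    noise: float = 1.0
    model: int = 1
    isoform_count_lambda: float = 3.0
    n_switching: int = 2
    gene_mean_source: Sequence[float] | tuple[float, float] | None = None
    transition_matrix: np.ndarray = field(
        default_factory=lambda: DEFAULT_TRANSITIONS.copy()
    )
    seed: int = 0

    def __post_init__(self) -> None:
        tm = np.asarray(self.transition_matrix, dtype=float)
        if tm.shape != (2, 2) or np.any(tm < 0) or not np.allclose(tm.sum(1), 1.0):
            raise ValueError("transition_matrix must be 2x2 row-stochastic")
        self.transition_matrix = tm
        if self.n_timepoints < 2:
            raise ValueError("need at least two time points")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if self.noise <= 0:
            raise ValueError("noise must be positive")
        if self.model not in (1, 2):
            raise ValueError("model must be 1 or 2")


@dataclass
class SimulatedDataset:
    """Simulator output: expression matrix plus per-gene ground truth."""

    matrix: TimeCourseMatrix
    truth_genes: set[str]
    truth_switch_times: dict[str, list[int]]
    truth_isoform_pairs: dict[str, tuple[str, str]]
    state_paths: dict[str, np.ndarray]
    abundance_params: dict[str, np.ndarray]


def _gene_rngs(seed: int, n_genes: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n_genes)]


def sample_state_path(
    T: int, transition_matrix: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One length-``T`` 0/1 state sequence, starting unswitched (0)."""
    tm = np.asarray(transition_matrix, dtype=float)
    states = np.zeros(T, dtype=int)
    for t in range(1, T):
        prev = states[t - 1]
        flip = rng.random() < tm[prev, 1 - prev]
        states[t] = 1 - prev if flip else prev
    return states


def sample_state_paths(cfg: SimulationConfig) -> dict[str, np.ndarray]:
    """State sequences for every gene (diagnostic entry point).

    ``simulate`` draws its own paths from per-gene substreams; this function
    exposes the same sampler for statistical checks.
    """
    rngs = _gene_rngs(cfg.seed, cfg.n_genes)
    return {
        f"g{i}": sample_state_path(cfg.n_timepoints, cfg.transition_matrix, rngs[i])
        for i in range(cfg.n_genes)
    }


def sample_isoform_probabilities(
    n_isoforms: int,
    n_switching: int,
    model: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, tuple[int, int]]:
    """Draw (unswitched, switched) fraction vectors and the swapped pair.

    The switched vector is the unswitched Dirichlet draw with one isoform
    pair's probabilities exchanged; e.g. under Model 1 the unswitched vector
    ``[0.03, 0.07, 0.1, 0.3, 0.5]`` becomes ``[0.03, 0.07, 0.1, 0.5, 0.3]``.
    """
    k = int(n_isoforms)
    if k < 2:
        raise ValueError("need at least two isoforms to define a switch")
    if model == 1:
        s = min(max(int(n_switching), 2), k)
        alpha = np.concatenate(
            [np.ones(k - s), 10.0 * np.arange(1, s + 1)]
        )
    elif model == 2:
        alpha = 10.0 * np.arange(1, k + 1)
    else:
        raise ValueError("model must be 1 or 2")
    p_unswitched = rng.dirichlet(alpha)
    if model == 1:
        # two highest-alpha isoforms are at fixed positions k-2, k-1
        pair = (k - 2, k - 1)
    else:
        candidates = np.flatnonzero(p_unswitched > 0.3)
        if len(candidates) >= 2:
            pair = tuple(sorted(rng.choice(candidates, size=2, replace=False)))
        else:
            pair = tuple(np.argsort(p_unswitched)[-2:])
    p_switched = apply_switch(p_unswitched, pair)
    return p_unswitched, p_switched, (int(pair[0]), int(pair[1]))


def apply_switch(probabilities: np.ndarray, pair: tuple[int, int] | None = None) -> np.ndarray:
    """Swap the probabilities of one isoform pair (default: the two largest).

    This is the Model 1 switch-introduction rule applied to a concrete
    fraction vector.
    """
    p = np.asarray(probabilities, dtype=float).copy()
    if pair is None:
        pair = tuple(np.argsort(p)[-2:])
    i, j = pair
    p[i], p[j] = p[j], p[i]
    return p


def sample_counts(
    prob_per_timepoint: np.ndarray,
    gene_mean: float,
    noise: float,
    n_replicates: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Noisy replicate expression for one gene.

    Parameters
    ----------
    prob_per_timepoint
        ``(T, k)`` state-dependent isoform fraction vectors.
    gene_mean
        Total gene expression level; transcript means are fractions times
        this value.

    Returns
    -------
    ``(k, T * n_replicates)`` non-negative expression values, columns
    time-major, replicate-minor.
    """
    if gene_mean <= 0:
        raise ValueError("gene_mean must be positive")
    if noise <= 0:
        raise ValueError("noise must be positive")
    probs = np.asarray(prob_per_timepoint, dtype=float)
    T, k = probs.shape
    mu = probs * gene_mean  # (T, k)
    theta = rng.gamma(shape=mu + noise, scale=noise)  # variance, (T, k)
    reps = rng.normal(
        loc=mu[:, :, None], scale=np.sqrt(theta)[:, :, None], size=(T, k, n_replicates)
    )
    np.clip(reps, 0.0, None, out=reps)
    # (T, k, R) -> (k, T*R) time-major
    return reps.transpose(1, 0, 2).reshape(k, T * n_replicates)


def _draw_gene_mean(cfg: SimulationConfig, rng: np.random.Generator) -> float:
    src = cfg.gene_mean_source
    if src is None:
        src = (np.log(1000.0), 0.8)
    if isinstance(src, tuple) and len(src) == 2 and np.isscalar(src[0]):
        return float(max(rng.lognormal(mean=src[0], sigma=src[1]), 1.0))
    means = np.asarray(src, dtype=float)
    if np.any(means <= 0):
        raise ValueError("gene means must be positive")
    return float(means[rng.integers(len(means))])


def simulate(cfg: SimulationConfig) -> SimulatedDataset:
    """Run the full generative model; deterministic given ``cfg.seed``."""
    rngs = _gene_rngs(cfg.seed, cfg.n_genes)
    T, R = cfg.n_timepoints, cfg.n_replicates

    all_values: list[np.ndarray] = []
    transcript_ids: list[str] = []
    gene_map: dict[str, str] = {}
    truth_genes: set[str] = set()
    truth_switch_times: dict[str, list[int]] = {}
    truth_isoform_pairs: dict[str, tuple[str, str]] = {}
    state_paths: dict[str, np.ndarray] = {}
    abundance_params: dict[str, np.ndarray] = {}

    for gi in range(cfg.n_genes):
        rng = rngs[gi]
        gene = f"g{gi}"
        k = max(int(rng.poisson(cfg.isoform_count_lambda)), 1)
        states = sample_state_path(T, cfg.transition_matrix, rng)
        if k < 2:
            states = np.zeros(T, dtype=int)  # background gene, cannot switch
        gene_mean = _draw_gene_mean(cfg, rng)

        tids = [f"{gene}.t{j + 1}" for j in range(k)]
        if k >= 2:
            p_u, p_s, pair = sample_isoform_probabilities(
                k, cfg.n_switching, cfg.model, rng
            )
            probs = np.where(states[:, None] == 1, p_s[None, :], p_u[None, :])
            abundance_params[gene] = p_u
        else:
            probs = np.ones((T, 1))
            abundance_params[gene] = np.ones(1)
            pair = None

        counts = sample_counts(probs, gene_mean, cfg.noise, R, rng)
        all_values.append(counts)
        transcript_ids.extend(tids)
        gene_map.update({t: gene for t in tids})
        state_paths[gene] = states

        flips = [t - 1 for t in range(1, T) if states[t] != states[t - 1]]
        if flips:
            truth_genes.add(gene)
            truth_switch_times[gene] = flips
            truth_isoform_pairs[gene] = (tids[pair[0]], tids[pair[1]])

    matrix = TimeCourseMatrix(
        values=np.vstack(all_values),
        transcript_ids=transcript_ids,
        time_points=[f"t{t}" for t in range(T)],
        n_replicates=R,
        gene_map=gene_map,
    )
    return SimulatedDataset(
        matrix=matrix,
        truth_genes=truth_genes,
        truth_switch_times=truth_switch_times,
        truth_isoform_pairs=truth_isoform_pairs,
        state_paths=state_paths,
        abundance_params=abundance_params,
    )


# ---------------------------------------------------------------------------
# On-disk form
# ---------------------------------------------------------------------------

def write_dataset(ds: SimulatedDataset, out_dir: str | Path) -> None:
    """Write expression, gene map and truth tables as TSV files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_expression(ds.matrix, out / "expression.tsv")
    write_gene_map(ds.matrix.gene_map, out / "gene_map.tsv")
    pd.DataFrame({"gene_id": sorted(ds.truth_genes)}).to_csv(
        out / "truth_genes.tsv", sep="\t", index=False
    )
    rows = [
        {
            "gene_id": g,
            "switch_times": ";".join(map(str, ds.truth_switch_times[g])),
            "isoform_a": ds.truth_isoform_pairs[g][0],
            "isoform_b": ds.truth_isoform_pairs[g][1],
        }
        for g in sorted(ds.truth_genes)
    ]
    pd.DataFrame(rows, columns=["gene_id", "switch_times", "isoform_a", "isoform_b"]).to_csv(
        out / "switch_times.tsv", sep="\t", index=False
    )


def load_truth(sim_dir: str | Path) -> set[str]:
    """Read the truth gene set written by :func:`write_dataset`."""
    df = pd.read_csv(Path(sim_dir) / "truth_genes.tsv", sep="\t")
    return set(df["gene_id"].astype(str))
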