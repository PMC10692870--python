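"""Study-effect-free count generation from the fitted posterior.

Counts are regenerated from the population-level (fixed) cell-type effects
only — dataset random intercepts are excluded — so the output carries the
cell-type signal without study structure.  One generated sample is emitted per
raw sample, reusing its exposure so library-size structure is preserved.  As a
regularization, each generated count is constrained to the central credible
interval (80% by default) of the fixed-effects-only posterior-predictive
marginal of its (sample, gene) pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalogue import COLUMNS
from .model import DesignInfo, PosteriorDraws

ADJUSTED_SENTINEL = "adjusted"


@dataclass
class AdjustedDataset:
    """Generated study-effect-free counts plus their credible-interval bounds.

    ``table`` is a canonical long-format catalogue whose dataset column is the
    sentinel "adjusted"; ``intervals`` stores the per (sample, gene) bounds the
    counts were constrained to; ``source`` maps each generated sample to the
    raw sample (and its dataset) it mirrors; ``prior_only_genes`` lists genes
    never observed for some cell type, whose draws are prior-informed.
    """

    table: pd.DataFrame
    intervals: pd.DataFrame
    source: pd.DataFrame
    prior_only_genes: dict[str, list[str]]

    def wide_matrix(self) -> pd.DataFrame:
        """Gene x sample matrix (GeneSymbol first column; celltype.replicate columns)."""
        wide = self.table.pivot_table(index="gene", columns="sample", values="count")
        wide.index.name = "GeneSymbol"
        return wide


def generate_adjusted_counts(
    draws: PosteriorDraws,
    design: DesignInfo,
    credible_mass: float = 0.80,
    seed: int = 0,
    mode: str = "reject",
    n_predictive: int = 400,
    max_redraws: int = 1000,
) -> AdjustedDataset:
    """Posterior-predictive counts from fixed effects only, within the credible interval.

    For raw sample s (cell type c, exposure eps_s) and gene g, predictive draws
    are Y* ~ NB(exp(alpha_{g,c}^(d) + eps_s), exp(sigma_g^(d))) over posterior
    draws d.  The central ``credible_mass`` interval of that marginal is taken
    from ``n_predictive`` Monte-Carlo draws; the emitted count is redrawn until
    it falls inside (``mode="reject"``, capped at ``max_redraws`` then clamped
    to the nearest bound) or clamped directly (``mode="clamp"``).
    Deterministic under ``seed``.
    """
    if draws.n_draws == 0:
        raise ValueError("posterior draws are empty")
    if not 0 < credible_mass < 1:
        raise ValueError("credible_mass must lie in (0, 1)")
    if mode not in {"reject", "clamp"}:
        raise ValueError("mode must be 'reject' or 'clamp'")
    rng = np.random.default_rng(seed)
    D = draws.n_draws
    S, G = design.S, design.G
    lo_q = (1.0 - credible_mass) / 2.0
    hi_q = 1.0 - lo_q

    theta_d = draws.theta  # (D, G)
    alpha_d = draws.alpha  # (D, G, C)

    # predictive Monte-Carlo ensemble per (s, g): (n_predictive, S, G)
    d_idx = rng.integers(0, D, size=(n_predictive, S))
    records = np.empty((S, G), dtype=np.int64)
    lower = np.empty((S, G), dtype=np.int64)
    upper = np.empty((S, G), dtype=np.int64)
    for s in range(S):
        c = design.cell_of[s]
        dd = d_idx[:, s]
        mu = np.exp(alpha_d[dd, :, c] + design.epsilon[s])  # (n_predictive, G)
        th = theta_d[dd, :]
        ens = rng.poisson(rng.gamma(th, mu / th))
        lo = np.floor(np.quantile(ens, lo_q, axis=0)).astype(np.int64)
        hi = np.ceil(np.quantile(ens, hi_q, axis=0)).astype(np.int64)
        degenerate = lo > hi
        if degenerate.any():
            med = np.median(ens, axis=0).astype(np.int64)
            lo[degenerate] = med[degenerate]
            hi[degenerate] = med[degenerate]
            warnings.warn(
                f"degenerate predictive interval for sample {design.samples[s]}; "
                "emitting the marginal median",
                RuntimeWarning,
            )
        lower[s], upper[s] = lo, hi

        def draw_once(size_idx):
            dd1 = rng.integers(0, D, size=size_idx.size)
            mu1 = np.exp(alpha_d[dd1, size_idx, c] + design.epsilon[s])
            th1 = theta_d[dd1, size_idx]
            return rng.poisson(rng.gamma(th1, mu1 / th1))

        gene_idx = np.arange(G)
        val = draw_once(gene_idx)
        if mode == "clamp":
            val = np.clip(val, lo, hi)
        else:
            outside = (val < lo) | (val > hi)
            tries = 0
            while outside.any() and tries < max_redraws:
                redo = gene_idx[outside]
                val[redo] = draw_once(redo)
                outside = (val < lo) | (val > hi)
                tries += 1
            if outside.any():
                val[outside] = np.clip(val[outside], lo[outside], hi[outside])
        records[s] = val

    samples_new, cell_labels, src_samples, src_datasets = [], [], [], []
    per_ct_counter: dict[str, int] = {}
    for s in range(S):
        ct = design.cell_types[design.cell_of[s]]
        per_ct_counter[ct] = per_ct_counter.get(ct, 0) + 1
        samples_new.append(f"{ct}.{per_ct_counter[ct]}")
        cell_labels.append(ct)
        src_samples.append(design.samples[s])
        src_datasets.append(design.datasets[design.dataset_of[s]])

    s_ix = np.repeat(np.arange(S), G)
    g_ix = np.tile(np.arange(G), S)
    table = pd.DataFrame(
        {
            "sample": [samples_new[i] for i in s_ix],
            "gene": [design.genes[j] for j in g_ix],
            "cell_type": [cell_labels[i] for i in s_ix],
            "dataset": ADJUSTED_SENTINEL,
            "count": records[s_ix, g_ix],
        }
    )[COLUMNS]
    intervals = pd.DataFrame(
        {
            "sample": [samples_new[i] for i in s_ix],
            "gene": [design.genes[j] for j in g_ix],
            "lower": lower[s_ix, g_ix],
            "upper": upper[s_ix, g_ix],
        }
    )
    source = pd.DataFrame(
        {"sample": samples_new, "source_sample": src_samples, "source_dataset": src_datasets}
    )

    prior_only: dict[str, list[str]] = {}
    for c, ct in enumerate(design.cell_types):
        rows = design.cell_of == c
        never = ~design.mask[rows].any(axis=0)
        if never.any():
            prior_only[ct] = [design.genes[j] for j in np.flatnonzero(never)]
    return AdjustedDataset(table=table, intervals=intervals, source=source, prior_only_genes=prior_only)
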