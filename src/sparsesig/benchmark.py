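"""In-silico mixture deconvolution benchmark.

Mixtures with known Dirichlet proportions are synthesized from cell-type
expression profiles, deconvolved by linear least-squares regression against a
signature matrix, and scored by mean absolute error, Jensen-Shannon divergence
(base-2 logs, bounded by 1) and Pearson correlation.  Marker specificity is
scored by the "second fold change": the ratio of a marker's abundance in its
highest- versus second-highest-expressing cell type.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# proportions & mixtures

def sample_dirichlet_proportions(
    n_mixtures: int, concentrations: np.ndarray, seed: int = 0,
    cell_types: list[str] | None = None,
) -> pd.DataFrame:
    """n_mixtures i.i.d. Dirichlet(concentrations) rows; reproducible by seed."""
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("Dirichlet concentrations must be positive")
    rng = np.random.default_rng(seed)
    P = rng.dirichlet(conc, size=n_mixtures)
    cols = cell_types if cell_types is not None else [f"ct{c}" for c in range(conc.size)]
    return pd.DataFrame(P, columns=cols, index=[f"mix{i:03d}" for i in range(n_mixtures)])


@dataclass
class MixtureExperiment:
    """Known proportions P (mixtures x cell types) and expression M (genes x mixtures)."""

    P: pd.DataFrame
    M: pd.DataFrame
    seed: int


def generate_mixture_from_proportion_matrix(
    profiles: pd.DataFrame,
    P: pd.DataFrame,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> MixtureExperiment:
    """Mix cell-type expression profiles by known proportions.

    M[g, i] = sum_c P[i, c] * profiles[g, c], optionally perturbed by
    multiplicative log-normal noise of log-SD ``noise_sd``.
    """
    missing = set(P.columns) - set(profiles.columns)
    extra = set(profiles.columns) - set(P.columns)
    if missing:
        raise ValueError(
            f"cell-type labels differ; in P but not profiles: {sorted(missing)}; "
            f"in profiles but not P: {sorted(extra)}"
        )
    prof = profiles[list(P.columns)]
    M = prof.to_numpy() @ P.to_numpy().T
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        M = M * rng.lognormal(0.0, noise_sd, size=M.shape)
    Mdf = pd.DataFrame(M, index=profiles.index, columns=P.index)
    return MixtureExperiment(P=P.copy(), M=Mdf, seed=seed)


# ---------------------------------------------------------------------------
# LLSR deconvolution

def deconvolve_llsr(M: pd.DataFrame, signature: pd.DataFrame) -> pd.DataFrame:
    """Linear least-squares deconvolution of mixtures against a signature.

    Per mixture: OLS of the mixture expression on the signature columns over
    shared genes; negative coefficients are clipped to zero and the vector is
    renormalized to sum to one.
    """
    shared = signature.index.intersection(M.index)
    C = signature.shape[1]
    if len(shared) < C:
        raise ValueError(f"need at least {C} shared genes, found {len(shared)}")
    S = signature.loc[shared].to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(S)
    if rank < C:
        corr = np.corrcoef(S.T)
        pairs = [
            (signature.columns[i], signature.columns[j])
            for i in range(C) for j in range(i + 1, C)
            if abs(corr[i, j]) > 1.0 - 1e-10
        ]
        raise ValueError(f"rank-deficient signature; collinear cell types: {pairs}")
    B = M.loc[shared].to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(S, B, rcond=None)  # (C, n_mixtures)
    coef = np.clip(coef, 0.0, None)
    sums = coef.sum(axis=0)
    sums[sums == 0] = 1.0
    coef = coef / sums
    return pd.DataFrame(coef.T, index=M.columns, columns=signature.columns)


# ---------------------------------------------------------------------------
# metrics

def mean_absolute_error(reference: np.ndarray, estimate: np.ndarray) -> float:
    """sum |ref_c - est_c| / C."""
    ref = np.asarray(reference, dtype=float)
    est = np.asarray(estimate, dtype=float)
    if ref.shape != est.shape or ref.size < 1:
        raise ValueError("reference and estimate must have equal nonzero length")
    return float(np.abs(ref - est).sum() / ref.size)


def jensen_shannon_divergence(P: np.ndarray, Q: np.ndarray) -> float:
    """Jensen-Shannon divergence with base-2 logs (bounded in [0, 1]); 0 log 0 := 0."""
    p = np.asarray(P, dtype=float)
    q = np.asarray(Q, dtype=float)
    if np.any(p < 0) or np.any(q < 0):
        raise ValueError("proportions must be nonnegative")
    m = 0.5 * (p + q)

    def kl(a, b):
        mask = a > 0
        return float(np.sum(a[mask] * np.log2(a[mask] / b[mask])))

    return 0.5 * kl(p, m) + 0.5 * kl(q, m)


def second_fold_change(
    profiles: pd.DataFrame,
    marker_assignments: dict[str, str] | pd.Series | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Marker specificity score: (top + e0) / (second + e0) per gene.

    Cell types are ranked per gene by descending mean abundance; the score is
    the pseudocounted ratio of the top to the second cell type.  When marker
    assignments are given, ``top_matches_assignment`` reports whether the
    highest-expressing cell type is the marker's assigned one.
    """
    if profiles.shape[1] < 2:
        raise ValueError("second fold change needs at least 2 cell types")
    if np.any(profiles.to_numpy() < 0):
        raise ValueError("profiles must be nonnegative")
    vals = profiles.to_numpy(dtype=float)
    order = np.argsort(-vals, axis=1, kind="stable")
    top = vals[np.arange(len(vals)), order[:, 0]]
    second = vals[np.arange(len(vals)), order[:, 1]]
    score = (top + pseudocount) / (second + pseudocount)
    out = pd.DataFrame(
        {
            "gene": profiles.index,
            "top_cell_type": profiles.columns.to_numpy()[order[:, 0]],
            "second_cell_type": profiles.columns.to_numpy()[order[:, 1]],
            "score": score,
        }
    ).set_index("gene")
    if marker_assignments is not None:
        assigned = pd.Series(marker_assignments)
        out["assigned_cell_type"] = assigned.reindex(out.index)
        out["top_matches_assignment"] = out["top_cell_type"] == out["assigned_cell_type"]
    return out


@dataclass
class BenchmarkResult:
    """Per-mixture scores and their medians across mixtures."""

    per_mixture: pd.DataFrame  # columns: mae, jsd, pearson_r
    medians: pd.Series


def evaluate_deconvolution(truth: pd.DataFrame, estimates: pd.DataFrame) -> BenchmarkResult:
    """MAE, JSD and Pearson r per mixture, summarized by medians across mixtures."""
    if list(truth.columns) != list(estimates.columns) or list(truth.index) != list(estimates.index):
        raise ValueError("truth and estimates must share mixture and cell-type labels")
    rows = []
    for mix in truth.index:
        t = truth.loc[mix].to_numpy(dtype=float)
        e = estimates.loc[mix].to_numpy(dtype=float)
        if np.ptp(t) == 0 or np.ptp(e) == 0:
            r = np.nan
        else:
            r = float(stats.pearsonr(t, e)[0])
        rows.append((mean_absolute_error(t, e), jensen_shannon_divergence(t, e), r))
    per = pd.DataFrame(rows, index=truth.index, columns=["mae", "jsd", "pearson_r"])
    return BenchmarkResult(per_mixture=per, medians=per.median())


# ---------------------------------------------------------------------------
# signature construction from a catalogue

def celltype_profiles(table: pd.DataFrame, scale: str = "cpm") -> pd.DataFrame:
    """Gene x cell-type mean expression profiles from a long catalogue.

    Counts are CPM-scaled per sample (missing pairs stay missing) and averaged
    over the samples of each cell type.
    """
    wide = table.pivot_table(index="sample", columns="gene", values="count")
    if scale == "cpm":
        wide = wide.div(wide.sum(axis=1, skipna=True), axis=0) * 1e6
    ann = table[["sample", "cell_type"]].drop_duplicates().set_index("sample")["cell_type"]
    prof = wide.groupby(ann.reindex(wide.index).to_numpy()).mean()
    return prof.T  # genes x cell types


def build_signature(table: pd.DataFrame, n_markers: int = 200) -> pd.DataFrame:
    """Signature matrix: top markers by second-fold-change over per-cell-type means.

    Genes observed in every cell type are ranked by the second-fold-change of
    their CPM profile; the ``n_markers`` top-ranked genes form the signature.
    """
    prof = celltype_profiles(table)
    complete = prof.dropna()
    scores = second_fold_change(complete)
    top = scores.sort_values("score", ascending=False, kind="stable").index[:n_markers]
    return complete.loc[top]


def read_signature(path: str) -> pd.DataFrame:
    sig = pd.read_csv(path, sep="\t")
    return sig.set_index(sig.columns[0]).rename_axis("GeneSymbol")


def write_signature(sig: pd.DataFrame, path: str) -> None:
    out = sig.copy()
    out.index.name = "GeneSymbol"
    out.to_csv(path, sep="\t")
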