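"""Reading, validation, harmonization and normalization of count catalogues.

A catalogue is a long-format table of cell-type-resolved RNA-seq counts pooled
from many studies.  Each row is one observed (sample, gene) pair; pairs that a
study did not measure are simply absent (structured missingness), never zero.
The canonical columns are ``sample``, ``gene``, ``cell_type``, ``dataset`` and
``count``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COLUMNS = ["sample", "gene", "cell_type", "dataset", "count"]


class CatalogueValidationError(ValueError):
    """Raised when a catalogue violates the long-format count-table contract."""


def validate_observation_table(table: pd.DataFrame, *, allow_duplicates: bool = False) -> pd.DataFrame:
    """Validate the long-format catalogue contract and return the table.

    Checks column presence, count non-negativity/integrality, uniqueness of
    (sample, gene) pairs and that each sample carries a single
    (cell_type, dataset) annotation.
    """
    missing = [c for c in COLUMNS if c not in table.columns]
    if missing:
        raise CatalogueValidationError(f"missing required columns: {missing}")
    counts = table["count"]
    bad = ~np.isfinite(pd.to_numeric(counts, errors="coerce"))
    bad |= pd.to_numeric(counts, errors="coerce").fillna(-1) < 0
    with np.errstate(invalid="ignore"):
        nonint = pd.to_numeric(counts, errors="coerce") % 1 != 0
    bad |= nonint.fillna(True)
    if bad.any():
        rows = table.index[bad].tolist()[:10]
        raise CatalogueValidationError(
            f"counts must be nonnegative integers; offending rows (first 10): {rows}"
        )
    if not allow_duplicates:
        dup = table.duplicated(subset=["sample", "gene"], keep=False)
        if dup.any():
            pairs = table.loc[dup, ["sample", "gene"]].drop_duplicates().head(5)
            raise CatalogueValidationError(
                f"duplicate (sample, gene) pairs, e.g.:\n{pairs.to_string(index=False)}"
            )
    ann = table[["sample", "cell_type", "dataset"]].drop_duplicates()
    multi = ann["sample"].duplicated(keep=False)
    if multi.any():
        offenders = sorted(ann.loc[multi, "sample"].unique())[:5]
        raise CatalogueValidationError(
            f"samples with conflicting (cell_type, dataset) annotation: {offenders}"
        )
    return table


def read_catalogue(path: str) -> pd.DataFrame:
    """Read a catalogue TSV/CSV (delimiter sniffed from the extension)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    table = pd.read_csv(path, sep=sep, dtype={"sample": str, "gene": str, "cell_type": str, "dataset": str})
    return validate_observation_table(table, allow_duplicates=True)


def write_catalogue(table: pd.DataFrame, path: str) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    table.to_csv(path, sep=sep, index=False)


def read_gene_keymap(path: str) -> pd.DataFrame:
    """Read a 2-column (source_id, gene_symbol) TSV, preserving row order."""
    km = pd.read_csv(path, sep="\t", dtype=str)
    km.columns = ["source_id", "gene_symbol"][: len(km.columns)]
    if km.shape[1] < 2:
        raise CatalogueValidationError("gene keymap needs 2 columns: source_id, gene_symbol")
    return km


def aggregate_duplicate_features(
    table: pd.DataFrame, keymap: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Resolve gene identifiers and collapse duplicated (sample, gene) rows.

    When a keymap is given, each source id is translated to a symbol using the
    *first* keymap entry for that id; rows whose id has no mapping are dropped.
    Rows that then share a (sample, gene) key are aggregated by summing counts,
    preserving sequencing-depth semantics.  Idempotent.
    """
    validate_observation_table(table, allow_duplicates=True)
    table = table.copy()
    if keymap is not None:
        if len(keymap) == 0:
            raise CatalogueValidationError("gene keymap is empty")
        first = keymap.drop_duplicates(subset="source_id", keep="first")
        lut = dict(zip(first["source_id"], first["gene_symbol"]))
        table["gene"] = table["gene"].map(lut)
        table = table.dropna(subset=["gene"])
        table = table[table["gene"].astype(str).str.len() > 0]
    grouped = (
        table.groupby(["sample", "gene", "cell_type", "dataset"], sort=False, as_index=False)["count"]
        .sum()
    )
    out = grouped[COLUMNS].reset_index(drop=True)
    return validate_observation_table(out)


def _wide_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Samples x genes matrix; absent pairs become NaN (missing, not zero)."""
    return table.pivot_table(index="sample", columns="gene", values="count", aggfunc="sum")


def remove_redundant_samples(
    table: pd.DataFrame,
    threshold: float = 0.99,
    n_top_genes: int = 1000,
    min_shared_genes: int = 50,
) -> tuple[pd.DataFrame, list[str]]:
    """Drop near-duplicate samples within each dataset.

    Within each dataset the ``n_top_genes`` most-variable genes (variance of
    log1p counts-per-million) are selected; pairwise Pearson correlations over
    genes observed in both samples are computed, and for each pair with
    r > ``threshold`` the lexicographically later sample is dropped.  Pairs
    sharing fewer than ``min_shared_genes`` of the selected genes are never
    declared redundant.  Samples are never compared across datasets.

    Returns the retained table and the list of removed sample ids.
    """
    validate_observation_table(table)
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    removed: list[str] = []
    for _, sub in table.groupby("dataset", sort=True):
        wide = _wide_counts(sub)
        if wide.shape[0] < 2:
            continue
        libsize = wide.sum(axis=1, skipna=True)
        cpm = wide.div(libsize, axis=0) * 1e6
        logcpm = np.log1p(cpm)
        variances = logcpm.var(axis=0, skipna=True)
        top = variances.sort_values(ascending=False, kind="stable").index[:n_top_genes]
        sel = logcpm[top]
        samples = sorted(sel.index)  # lexicographic: later member of a pair dropped
        dropped: set[str] = set()
        for i, a in enumerate(samples):
            if a in dropped:
                continue
            for b in samples[i + 1 :]:
                if b in dropped:
                    continue
                both = sel.loc[a].notna() & sel.loc[b].notna()
                if both.sum() < min_shared_genes:
                    continue
                x, y = sel.loc[a, both], sel.loc[b, both]
                if x.std() == 0 or y.std() == 0:
                    r = 1.0 if np.allclose(x, y) else 0.0
                else:
                    r = float(np.corrcoef(x, y)[0, 1])
                if r > threshold:
                    dropped.add(b)
                    removed.append(b)
    kept = table[~table["sample"].isin(removed)].reset_index(drop=True)
    return kept, sorted(removed)


@dataclass
class ExposureVector:
    """Per-sample sequencing-depth offsets.

    ``epsilon`` is the log effective library size (TMM factor x library size),
    centered to mean zero across samples so exposure is identifiable against
    the gene-level intercepts.
    """

    samples: list[str]
    tmm_factor: np.ndarray
    library_size: np.ndarray
    epsilon: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.epsilon is None:
            eff = np.log(self.tmm_factor * self.library_size)
            self.epsilon = eff - eff.mean()

    def as_series(self) -> pd.Series:
        return pd.Series(self.epsilon, index=pd.Index(self.samples, name="sample"))


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float = 0.30,
    abundance_trim: float = 0.05,
) -> float:
    """Trimmed mean of M-values of one library against the reference.

    Follows the published TMM recipe: genes positive in both libraries; M/A in
    log2 of depth-scaled counts; two-sided trimming of 30% on M and 5% on A;
    delta-method precision weights on the trimmed mean.
    """
    both = (obs > 0) & (ref > 0) & np.isfinite(obs) & np.isfinite(ref)
    o, r = obs[both], ref[both]
    if o.size == 0:
        return 1.0
    po, pr = o / lib_obs, r / lib_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    w = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    finite = np.isfinite(m) & np.isfinite(a)
    m, a, w = m[finite], a[finite], w[finite]
    n = m.size
    if n == 0:
        return 1.0
    if np.max(np.abs(m)) < 1e-6:  # identical relative composition
        return 1.0
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abundance_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.nansum(m[keep] / w[keep]) / np.nansum(1.0 / w[keep])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0**f)


def compute_exposure(table: pd.DataFrame) -> ExposureVector:
    """TMM factors, effective library sizes and centered log exposures.

    The reference library is the sample whose 75th-percentile count fraction is
    closest to the across-sample mean of that quantity; factors are scaled so
    their geometric mean is 1 (missing pairs are ignored throughout).
    """
    validate_observation_table(table)
    wide = _wide_counts(table)
    libsize = wide.sum(axis=1, skipna=True).to_numpy()
    zero = libsize <= 0
    if zero.any():
        bad = [wide.index[i] for i in np.flatnonzero(zero)]
        raise CatalogueValidationError(f"samples with all-zero counts: {bad}")
    mat = wide.to_numpy(dtype=float)
    f75 = np.array(
        [np.nanquantile(row, 0.75) / libsize[i] for i, row in enumerate(mat)]
    )
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.empty(len(libsize))
    for i in range(len(libsize)):
        both = np.isfinite(mat[i]) & np.isfinite(mat[ref_idx])
        factors[i] = _tmm_pair_factor(
            np.where(both, mat[i], np.nan),
            np.where(both, mat[ref_idx], np.nan),
            libsize[i],
            libsize[ref_idx],
        )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return ExposureVector(samples=list(wide.index), tmm_factor=factors, library_size=libsize)
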