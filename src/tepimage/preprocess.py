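"""Count-matrix ingestion, filtering, normalization and variance stabilization.

The pipeline starts from a gene-level RNA-seq count matrix (features x
samples).  Samples with shallow sequencing are removed, annotation-level
feature ids are collapsed to gene symbols, per-sample size factors are
estimated with the median-of-ratios convention, and counts are transformed
with a closed-form variance-stabilizing transformation (VST) driven by a
parametric dispersion-mean trend ``alpha(mu) = a0 + a1/mu`` fitted to
method-of-moments per-gene dispersions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "DispersionTrend",
    "EmptyCohortError",
    "filter_samples",
    "map_genes",
    "size_factors",
    "log_geometric_means",
    "fit_dispersion_trend",
    "vst",
    "read_counts_tsv",
    "read_annotation_tsv",
    "write_matrix_tsv",
]


class EmptyCohortError(ValueError):
    """Raised when a filtering step removes every sample or every feature."""


@dataclass
class CountMatrix:
    """Integer feature x sample count matrix.

    ``counts`` is a DataFrame indexed by feature id with one column per
    sample.  Values must be nonnegative integers; feature and sample ids
    must be unique.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.counts
        if not c.index.is_unique:
            raise ValueError("feature ids are not unique")
        if not c.columns.is_unique:
            raise ValueError("sample ids are not unique")
        values = c.to_numpy()
        if values.size and (values < 0).any():
            raise ValueError("counts contain negative values")
        if values.size and not np.array_equal(values, np.floor(values)):
            raise ValueError("counts contain non-integral values")
        # Normalize dtype so downstream arithmetic is exact.
        self.counts = c.astype(np.int64)

    @property
    def feature_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def totals(self) -> pd.Series:
        """Per-sample total read counts (column sums)."""
        return self.counts.sum(axis=0)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def n_features(self) -> int:
        return self.counts.shape[0]


@dataclass
class DispersionTrend:
    """Parametric dispersion-mean trend ``alpha(mu) = a0 + a1/mu``.

    ``a0`` is the asymptotic (high-expression) dispersion and ``a1`` the
    extra-Poisson term that dominates at low means.  ``per_gene_dispersion``
    keeps the raw method-of-moments estimates the trend was fitted to.
    """

    a0: float
    a1: float
    per_gene_dispersion: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if not np.isfinite(self.a0) or not np.isfinite(self.a1):
            raise ValueError(
                f"degenerate dispersion trend: a0={self.a0}, a1={self.a1}"
            )
        if self.a0 <= 0:
            raise ValueError("a0 must be positive")
        if self.a1 < 0:
            raise ValueError("a1 must be nonnegative")

    def alpha(self, mu):
        """Trend dispersion at mean ``mu``."""
        mu = np.asarray(mu, dtype=float)
        return self.a0 + self.a1 / np.maximum(mu, np.finfo(float).tiny)


def filter_samples(counts: CountMatrix, min_total: int = 100_000) -> CountMatrix:
    """Drop samples sequenced below ``min_total`` total reads.

    The comparison is strict: a sample with exactly ``min_total`` reads is
    retained.  Sample order is preserved.  Raises :class:`EmptyCohortError`
    if nothing survives.
    """
    totals = counts.totals
    keep = totals >= min_total
    removed = list(totals.index[~keep])
    if removed:
        logger.info(
            "filter_samples: removed %d sample(s) below %d total reads: %s",
            len(removed), min_total, removed,
        )
    if not keep.any():
        raise EmptyCohortError(
            f"all {counts.n_samples} samples fall below {min_total} total reads"
        )
    return CountMatrix(counts.counts.loc[:, keep])


def map_genes(counts: CountMatrix, annot: pd.DataFrame) -> CountMatrix:
    """Collapse annotation feature ids to gene symbols.

    ``annot`` must have columns ``source_id``, ``gene_name``, ``status``,
    ``level``.  Features whose status is not ``known`` are dropped, as are
    features absent from the annotation (their count is logged).  When
    several source ids map to one gene name the row with the smallest
    annotation level wins (level 1 is the highest-confidence tier); at equal
    level the row with the larger total count is kept.
    """
    required = {"source_id", "gene_name", "status", "level"}
    missing = required - set(annot.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    ann = annot.set_index("source_id")
    if not ann.index.is_unique:
        raise ValueError("annotation source_id values are not unique")

    in_annot = counts.feature_ids.isin(ann.index)
    n_unresolved = int((~in_annot).sum())
    if n_unresolved:
        logger.info("map_genes: dropped %d unannotated feature(s)", n_unresolved)

    sub = counts.counts.loc[counts.feature_ids[in_annot]]
    meta = ann.loc[sub.index]
    known = meta["status"] == "known"
    n_not_known = int((~known).sum())
    if n_not_known:
        logger.info(
            "map_genes: dropped %d feature(s) with status != 'known'", n_not_known
        )
    sub = sub.loc[known.values]
    meta = meta.loc[known.values]
    if sub.empty:
        raise EmptyCohortError("no features survive gene mapping")

    order = pd.DataFrame(
        {
            "gene_name": meta["gene_name"].to_numpy(),
            "level": meta["level"].to_numpy(),
            "total": sub.sum(axis=1).to_numpy(),
        },
        index=sub.index,
    )
    # Smallest level wins; ties broken by larger total count.
    ranked = order.sort_values(
        ["gene_name", "level", "total"], ascending=[True, True, False]
    )
    winners = ranked[~ranked["gene_name"].duplicated(keep="first")]
    n_dups = len(order) - len(winners)
    if n_dups:
        logger.info(
            "map_genes: resolved %d duplicate gene-name mapping(s) by level/total",
            n_dups,
        )
    out = sub.loc[winners.index].copy()
    out.index = pd.Index(winners["gene_name"], name="gene_name")
    out = out.loc[sorted(out.index)]
    return CountMatrix(out)


def log_geometric_means(counts: CountMatrix) -> pd.Series:
    """Per-feature log geometric mean across samples; -inf where any count is 0.

    Rows containing a zero are excluded from the size-factor reference set,
    which the -inf encodes.
    """
    values = counts.counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logs = np.log(values)
    lgm = np.where((values > 0).all(axis=1), logs.mean(axis=1), -np.inf)
    return pd.Series(lgm, index=counts.feature_ids)


def size_factors(
    counts: CountMatrix, log_geomeans: pd.Series | None = None
) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample the factor is the median over reference genes of
    ``count / geometric-mean(count across samples)``; reference genes are
    rows with no zero entry.  ``log_geomeans`` lets a frozen reference
    (e.g. computed on training samples) be applied to new samples.
    """
    if log_geomeans is None:
        log_geomeans = log_geometric_means(counts)
    else:
        log_geomeans = log_geomeans.reindex(counts.feature_ids)
    ref = np.isfinite(log_geomeans.to_numpy())
    if not ref.any():
        raise ValueError(
            "no gene has all-positive counts across samples; the "
            "median-of-ratios reference set is empty (pseudo-reference "
            "fallback is disabled by default)"
        )
    values = counts.counts.to_numpy(dtype=float)[ref]
    with np.errstate(divide="ignore"):
        log_ratios = np.log(values) - log_geomeans.to_numpy()[ref, None]
    # Median taken in ratio space: with an even reference count the two
    # middle ratios are averaged arithmetically, matching the
    # median-of-ratios definition exactly.
    sf = np.median(np.exp(log_ratios), axis=0)
    out = pd.Series(sf, index=counts.sample_ids, name="size_factor")
    if not np.isfinite(out).all() or (out <= 0).any():
        raise ValueError("non-positive or non-finite size factor estimated")
    return out


def _mom_dispersions(norm: np.ndarray) -> np.ndarray:
    """Method-of-moments dispersion per gene on size-factor-normalized counts."""
    mu = norm.mean(axis=1)
    s2 = norm.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (s2 - mu) / mu**2
    alpha = np.where(mu > 0, alpha, 0.0)
    return np.maximum(alpha, 0.0)


def fit_dispersion_trend(
    counts: CountMatrix,
    sf: pd.Series,
    a0_floor: float = 1e-4,
    outlier_log_units: float = 2.0,
    max_iter: int = 20,
) -> DispersionTrend:
    """Fit ``alpha(mu) = a0 + a1/mu`` to per-gene method-of-moments dispersions.

    The regression of ``alpha_g`` on ``1/mu_g`` is iteratively reweighted
    (weights ``1/fitted^2``, i.e. constant relative error, the natural
    weighting for gamma-like dispersion estimates).  After convergence,
    genes deviating from the fit by more than ``outlier_log_units`` natural
    log units are excluded once and the trend refitted.  ``a0`` is floored
    at ``a0_floor``.
    """
    if counts.n_features < 50:
        logger.warning(
            "fit_dispersion_trend: only %d genes; >=50 recommended",
            counts.n_features,
        )
    norm = counts.counts.to_numpy(dtype=float) / sf.reindex(
        counts.sample_ids
    ).to_numpy()
    mu = norm.mean(axis=1)
    alpha = _mom_dispersions(norm)
    per_gene = pd.Series(alpha, index=counts.feature_ids, name="dispersion")

    use = (alpha > 0) & (mu > 0)
    if use.sum() < 2:
        raise ValueError(
            "degenerate dispersion fit: fewer than 2 genes with positive "
            "method-of-moments dispersion"
        )
    y = alpha[use]
    x = 1.0 / mu[use]
    X = np.column_stack([np.ones_like(x), x])

    def _irls(Xm: np.ndarray, ym: np.ndarray) -> np.ndarray:
        coef, *_ = np.linalg.lstsq(Xm, ym, rcond=None)
        for _ in range(max_iter):
            fitted = np.maximum(Xm @ coef, 1e-8)
            w = 1.0 / fitted**2
            Xw = Xm * w[:, None]
            new, *_ = np.linalg.lstsq(Xw.T @ Xm, Xw.T @ ym, rcond=None)
            if np.allclose(new, coef, rtol=1e-6, atol=1e-12):
                coef = new
                break
            coef = new
        return coef

    coef = _irls(X, y)
    fitted = np.maximum(X @ coef, 1e-12)
    keep = np.abs(np.log(y) - np.log(fitted)) <= outlier_log_units
    n_out = int((~keep).sum())
    if n_out and keep.sum() >= 2:
        logger.info("fit_dispersion_trend: excluded %d outlier gene(s)", n_out)
        coef = _irls(X[keep], y[keep])

    a0 = float(max(coef[0], a0_floor))
    a1 = float(max(coef[1], 0.0))
    if not (np.isfinite(a0) and np.isfinite(a1)):
        raise ValueError(
            f"degenerate dispersion fit: a0={coef[0]!r}, a1={coef[1]!r}, "
            f"n_genes={use.sum()}, mean mu={mu[use].mean():.3g}"
        )
    return DispersionTrend(a0=a0, a1=a1, per_gene_dispersion=per_gene)


def vst(
    counts: CountMatrix, sf: pd.Series, trend: DispersionTrend
) -> pd.DataFrame:
    """Closed-form variance-stabilizing transformation.

    With ``u = count / size factor`` and trend parameters ``a0, a1`` the
    transform is::

        log2( (1 + a1 + 2*a0*u + 2*sqrt(a0*u*(1 + a1 + a0*u))) / (4*a0) )

    which is strictly increasing in ``u``, finite at ``u = 0``, and grows
    like ``log2(u)`` for large ``u`` so that doubling a large normalized
    count adds one unit.
    """
    u = counts.counts.to_numpy(dtype=float) / sf.reindex(
        counts.sample_ids
    ).to_numpy()
    values = vst_values(u, trend)
    return pd.DataFrame(values, index=counts.feature_ids, columns=counts.sample_ids)


def vst_values(u, trend: DispersionTrend):
    """Apply the VST formula to an array of normalized counts ``u >= 0``."""
    u = np.asarray(u, dtype=float)
    if (u < 0).any():
        raise ValueError("normalized counts must be nonnegative")
    a0, a1 = trend.a0, trend.a1
    inner = a0 * u * (1.0 + a1 + a0 * u)
    return np.log2((1.0 + a1 + 2.0 * a0 * u + 2.0 * np.sqrt(inner)) / (4.0 * a0))


# ---------------------------------------------------------------------------
# TSV interfaces


def _read_tsv_strict(path, n_cols_from_header: bool = True) -> list[list[str]]:
    rows: list[list[str]] = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if width is None:
                width = len(fields)
            elif len(fields) != width:
                raise ValueError(
                    f"{path}: ragged row at line {lineno}: expected "
                    f"{width} fields, got {len(fields)}"
                )
            rows.append(fields)
    if not rows:
        raise ValueError(f"{path}: empty file")
    return rows


def read_counts_tsv(path) -> CountMatrix:
    """Read a counts TSV: first column feature id, header row of sample ids."""
    rows = _read_tsv_strict(path)
    header = rows[0]
    sample_ids = header[1:]
    index, data = [], []
    for lineno, fields in enumerate(rows[1:], start=2):
        index.append(fields[0])
        try:
            data.append([int(v) for v in fields[1:]])
        except ValueError as exc:
            raise ValueError(f"{path}: non-integer count at line {lineno}") from exc
    df = pd.DataFrame(data, index=pd.Index(index, name=header[0]), columns=sample_ids)
    return CountMatrix(df)


def read_annotation_tsv(path) -> pd.DataFrame:
    """Read an annotation TSV with columns source_id, gene_name, status, level."""
    rows = _read_tsv_strict(path)
    df = pd.DataFrame(rows[1:], columns=rows[0])
    required = {"source_id", "gene_name", "status", "level"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing annotation columns {sorted(missing)}")
    df["level"] = df["level"].astype(int)
    if (df["level"] < 1).any():
        raise ValueError(f"{path}: annotation level must be >= 1")
    return df


def write_matrix_tsv(df: pd.DataFrame, path, index_name: str = "gene_name") -> None:
    df = df.copy()
    df.index.name = index_name
    df.to_csv(path, sep="\t")
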