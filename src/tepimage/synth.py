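"""Synthetic platelet-like RNA-seq cohorts and fixture pathway panels.

Counts are negative-binomial with a log-normal baseline mean distribution
(``lognormal(ln 50, 1)``), a dispersion-mean trend ``alpha(mu) = a0 + a1/mu``
(defaults 0.05 and 2.0), and log-normal library-size factors (sigma 0.2 on
the log scale).  A class effect of ``log2_fc`` is applied to every gene of
the designated signal pathways in case samples, with alternating sign per
gene so the image-level signal is textural rather than a uniform
brightness shift.  The annotation table marks all genes status "known",
level 1, and adds a small fraction of decoy rows (duplicate gene names at
level 2 and unknown-status features) to exercise the gene-mapping rules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import CATEGORY_ORDER, PathwayEntry, PathwayPanel, write_panel
from .preprocess import CountMatrix

logger = logging.getLogger(__name__)

__all__ = ["SimulationConfig", "make_fixture_panel", "simulate_counts"]


@dataclass
class SimulationConfig:
    n_case: int = 60
    n_control: int = 60
    n_genes: int = 2000
    signal_pathways: tuple[str, ...] = ()
    log2_fc: float = 1.0
    baseline_log_mean: float = float(np.log(50.0))
    baseline_log_sd: float = 1.0
    a0: float = 0.05
    a1: float = 2.0
    libsize_log_sd: float = 0.2
    decoy_frac: float = 0.02
    benign_control_frac: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_case, self.n_control, self.n_genes) < 1:
            raise ValueError("cohort sizes and n_genes must be >= 1")


def make_fixture_panel(
    n_cancer: int,
    n_signaling: int,
    n_metabolism: int,
    gene_pool: list[str],
    overlap_frac: float = 0.0,
    seed: int = 0,
    length_range: tuple[int, int] = (10, 80),
    gmt_path=None,
) -> PathwayPanel:
    """Build a random categorized panel from a gene pool.

    Pathway lengths are uniform over ``length_range``; ``overlap_frac`` of
    each pathway's slots (after the first pathway) are drawn from genes
    already placed elsewhere, guaranteeing pixel multiplicity >= 2 for at
    least one gene whenever it is positive.
    """
    if not (0 <= overlap_frac < 1):
        raise ValueError("overlap_frac must lie in [0, 1)")
    counts_by_cat = dict(
        zip(CATEGORY_ORDER, (n_cancer, n_signaling, n_metabolism))
    )
    n_total = sum(counts_by_cat.values())
    if n_total < 1:
        raise ValueError("panel must contain at least one pathway")
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    lengths = rng.integers(lo, hi + 1, size=n_total)
    max_fresh = int(lengths.sum())
    if len(gene_pool) < lengths.max():
        raise ValueError(
            f"gene pool of {len(gene_pool)} cannot fill a pathway of "
            f"length {lengths.max()}"
        )

    pool = list(gene_pool)
    used: list[str] = []
    entries: list[PathwayEntry] = []
    i = 0
    next_fresh = 0
    for category in CATEGORY_ORDER:
        for j in range(counts_by_cat[category]):
            length = int(lengths[i])
            n_shared = int(round(overlap_frac * length)) if entries else 0
            n_shared = min(n_shared, len(used))
            if next_fresh + (length - n_shared) > len(pool):
                raise ValueError(
                    "gene pool exhausted; reduce pathway count/length or "
                    "increase overlap_frac"
                )
            fresh = pool[next_fresh : next_fresh + (length - n_shared)]
            next_fresh += len(fresh)
            shared = (
                [used[t] for t in rng.choice(len(used), n_shared, replace=False)]
                if n_shared
                else []
            )
            genes = fresh + shared
            order = rng.permutation(len(genes))
            genes = tuple(genes[t] for t in order)
            used.extend(fresh)
            pid = f"path_{category}_{j:03d}"
            entries.append(PathwayEntry(pid, pid, category, genes))
            i += 1
    panel = PathwayPanel(entries)
    if gmt_path is not None:
        write_panel(panel, gmt_path)
    return panel


def simulate_counts(
    cfg: SimulationConfig, panel: PathwayPanel
) -> tuple[CountMatrix, pd.Series, pd.Series, pd.DataFrame]:
    """Simulate an NB count cohort with pathway-structured class signal.

    Returns ``(counts, labels, strata, annotation)``: counts keyed by
    synthetic source ids, binary labels (1 = case), strata labels splitting
    controls into healthy/benign subtypes, and the annotation table mapping
    source ids to gene names.
    """
    panel_ids = set(panel.pathway_ids)
    unknown = set(cfg.signal_pathways) - panel_ids
    if unknown:
        raise ValueError(f"signal pathways not in panel: {sorted(unknown)}")

    rng = np.random.default_rng(cfg.seed)
    panel_genes = sorted(panel.gene_set)
    n_fill = max(0, cfg.n_genes - len(panel_genes))
    fillers = [f"BG{i:05d}" for i in range(n_fill)]
    genes = panel_genes + fillers
    n_genes = len(genes)

    signal_genes = sorted(
        {
            g
            for e in panel.entries
            if e.pathway_id in cfg.signal_pathways
            for g in e.genes
        }
    )
    # Alternate effect sign along the sorted signal gene list.
    sign = {g: (1 if i % 2 == 0 else -1) for i, g in enumerate(signal_genes)}

    mu = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=n_genes)
    alpha = cfg.a0 + cfg.a1 / mu
    n_samples = cfg.n_case + cfg.n_control
    sf = rng.lognormal(0.0, cfg.libsize_log_sd, size=n_samples)

    sample_ids = [f"case_{i:03d}" for i in range(cfg.n_case)] + [
        f"ctrl_{i:03d}" for i in range(cfg.n_control)
    ]
    labels = pd.Series(
        [1] * cfg.n_case + [0] * cfg.n_control, index=sample_ids, name="label"
    )

    fc = np.ones((n_genes, n_samples))
    gene_index = {g: i for i, g in enumerate(genes)}
    case_cols = np.arange(cfg.n_case)
    for g in signal_genes:
        fc[gene_index[g], case_cols] = 2.0 ** (sign[g] * cfg.log2_fc)

    mean = mu[:, None] * fc * sf[None, :]
    # NB(mean m, dispersion a): numpy parameterization n = 1/a, p = n/(n+m).
    r = 1.0 / alpha[:, None]
    p = r / (r + mean)
    counts = rng.negative_binomial(np.broadcast_to(r, mean.shape), p)

    source_ids = [f"SRC{i:05d}" for i in range(n_genes)]
    annot_rows = [
        {"source_id": sid, "gene_name": g, "status": "known", "level": 1}
        for sid, g in zip(source_ids, genes)
    ]

    # Decoys: duplicate-name level-2 rows and unknown-status rows, with
    # their own low-count features in the matrix.
    n_decoy = int(round(cfg.decoy_frac * n_genes))
    decoy_counts = []
    decoy_ids = []
    if n_decoy:
        dup_targets = rng.choice(n_genes, size=n_decoy, replace=False)
        for t, gi in enumerate(dup_targets):
            sid = f"DUP{t:05d}"
            status = "known" if t % 2 == 0 else "novel"
            annot_rows.append(
                {
                    "source_id": sid,
                    "gene_name": genes[gi],
                    "status": status,
                    "level": 2,
                }
            )
            decoy_ids.append(sid)
            decoy_counts.append(rng.poisson(1.0, size=n_samples))

    matrix = pd.DataFrame(counts, index=source_ids, columns=sample_ids)
    if decoy_ids:
        matrix = pd.concat(
            [matrix, pd.DataFrame(decoy_counts, index=decoy_ids, columns=sample_ids)]
        )
    annot = pd.DataFrame(annot_rows)

    n_benign = int(round(cfg.benign_control_frac * cfg.n_control))
    control_subtype = ["benign"] * n_benign + ["healthy"] * (cfg.n_control - n_benign)
    strata = pd.Series(
        ["case"] * cfg.n_case + control_subtype, index=sample_ids, name="stratum"
    )
    logger.info(
        "simulate_counts: %d genes (+%d decoys) x %d samples, %d signal genes",
        n_genes, len(decoy_ids), n_samples, len(signal_genes),
    )
    return CountMatrix(matrix), labels, strata, annot
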