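"""Categorized pathway panels and expression-to-image conversion.

A panel is an ordered collection of pathways in three blocks — cancer,
signaling, metabolism — each with an ordered member-gene list.  A sample's
normalized expression vector becomes a single-channel image with one row
per pathway and one column per gene position; a gene belonging to several
pathways contributes one pixel per membership.  Pixel intensity is a global
min-max rescaling of the transformed expression, clipped to [0, 1]; short
rows are zero-padded on the right, which renders as black like an absent
transcript.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
from PIL import Image

logger = logging.getLogger(__name__)

__all__ = [
    "CATEGORY_ORDER",
    "PathwayEntry",
    "PathwayPanel",
    "IntensityScaler",
    "SampleImage",
    "read_panel",
    "write_panel",
    "prune_panel",
    "fit_scaler",
    "build_image",
    "build_images",
    "export_png",
    "save_image_container",
    "load_image_container",
]

CATEGORY_ORDER = ("cancer", "signaling", "metabolism")


@dataclass(frozen=True)
class PathwayEntry:
    pathway_id: str
    display_name: str
    category: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.category not in CATEGORY_ORDER:
            raise ValueError(f"unknown pathway category: {self.category!r}")


@dataclass
class PathwayPanel:
    """Ordered pathway collection: cancer block first, then signaling, then
    metabolism; file order preserved within a block."""

    entries: list[PathwayEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.pathway_id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate pathway ids in panel")
        # Stable sort: canonical category order, file order within category.
        self.entries = sorted(
            self.entries, key=lambda e: CATEGORY_ORDER.index(e.category)
        )

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def pathway_ids(self) -> list[str]:
        return [e.pathway_id for e in self.entries]

    @property
    def max_length(self) -> int:
        return max(len(e.genes) for e in self.entries)

    @property
    def gene_set(self) -> set[str]:
        return {g for e in self.entries for g in e.genes}

    def gene_multiplicity(self, gene: str) -> int:
        """Number of panel rows the gene appears in (pixel multiplicity)."""
        return sum(gene in e.genes for e in self.entries)

    def category_counts(self) -> dict[str, int]:
        out = {c: 0 for c in CATEGORY_ORDER}
        for e in self.entries:
            out[e.category] += 1
        return out


def read_panel(path) -> PathwayPanel:
    """Parse a GMT-dialect panel file.

    Each line: ``pathway_id TAB description TAB gene1 TAB gene2 ...`` where
    the description field is the category token (``cancer`` / ``signaling``
    / ``metabolism``), optionally followed by ``|display name``.
    """
    entries: list[PathwayEntry] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: pathway has an empty gene list"
                )
            pathway_id, desc = fields[0], fields[1]
            category, _, display = desc.partition("|")
            category = category.strip().lower()
            if category not in CATEGORY_ORDER:
                raise ValueError(
                    f"{path}: line {lineno}: unknown category token "
                    f"{category!r} (expected one of {CATEGORY_ORDER})"
                )
            if pathway_id in seen:
                raise ValueError(
                    f"{path}: line {lineno}: duplicated pathway_id {pathway_id!r}"
                )
            seen.add(pathway_id)
            genes = tuple(g for g in fields[2:] if g)
            if not genes:
                raise ValueError(
                    f"{path}: line {lineno}: pathway has an empty gene list"
                )
            entries.append(
                PathwayEntry(pathway_id, display or pathway_id, category, genes)
            )
    return PathwayPanel(entries)


def write_panel(panel: PathwayPanel, path) -> None:
    """Write the panel back to the GMT dialect read by :func:`read_panel`."""
    with open(path, "w") as fh:
        for e in panel.entries:
            desc = e.category
            if e.display_name != e.pathway_id:
                desc += f"|{e.display_name}"
            fh.write("\t".join([e.pathway_id, desc, *e.genes]) + "\n")


def prune_panel(panel: PathwayPanel, expressed: set[str]) -> PathwayPanel:
    """Restrict every gene list to ``expressed`` genes, preserving order.

    Pathways left empty are dropped with a warning; an entirely empty
    result is an error.
    """
    kept: list[PathwayEntry] = []
    n_dropped = 0
    for e in panel.entries:
        genes = tuple(g for g in e.genes if g in expressed)
        if genes:
            kept.append(PathwayEntry(e.pathway_id, e.display_name, e.category, genes))
        else:
            n_dropped += 1
            logger.warning(
                "prune_panel: pathway %s has no expressed genes; dropped",
                e.pathway_id,
            )
    if not kept:
        raise ValueError("pruning left no non-empty pathway")
    if n_dropped:
        logger.warning("prune_panel: dropped %d empty pathway(s)", n_dropped)
    out = PathwayPanel(kept)
    logger.info(
        "prune_panel: %d pathways, image %d x %d", len(out), len(out), out.max_length
    )
    return out


@dataclass(frozen=True)
class IntensityScaler:
    """Global intensity bounds of transformed expression on a reference set."""

    v_min: float
    v_max: float

    def __post_init__(self) -> None:
        if not self.v_max > self.v_min:
            raise ValueError(
                f"degenerate scaler: v_max ({self.v_max}) must exceed "
                f"v_min ({self.v_min})"
            )

    def scale(self, values):
        """Map values into [0, 1], clipping outside the fitted range."""
        x = (np.asarray(values, dtype=float) - self.v_min) / (self.v_max - self.v_min)
        return np.clip(x, 0.0, 1.0)

    def to_json(self) -> str:
        return json.dumps({"v_min": self.v_min, "v_max": self.v_max})

    @classmethod
    def from_json(cls, text: str) -> "IntensityScaler":
        d = json.loads(text)
        return cls(v_min=d["v_min"], v_max=d["v_max"])


def fit_scaler(train_values: pd.DataFrame) -> IntensityScaler:
    """Global min-max over training samples x panel genes."""
    arr = train_values.to_numpy(dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values to fit an intensity scaler")
    v_min, v_max = float(arr.min()), float(arr.max())
    if v_min == v_max:
        raise ValueError("constant expression values: scaler undefined")
    return IntensityScaler(v_min=v_min, v_max=v_max)


@dataclass
class SampleImage:
    """Single-channel pathway-panel image for one sample.

    ``grid`` is H x W with H = number of pathways and W = longest pathway
    length; entries beyond a row's pathway length are zero padding.
    """

    sample_id: str
    grid: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        if g.ndim != 2:
            raise ValueError("image grid must be 2-D")
        if (g < 0).any() or (g > 1).any():
            raise ValueError("image values must lie in [0, 1]")
        self.grid = g

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape


def build_image(
    sample: pd.Series, panel: PathwayPanel, scaler: IntensityScaler
) -> SampleImage:
    """Convert one sample's expression vector into a pathway-panel image.

    The panel must already be pruned against the vector's gene set; a panel
    gene missing from ``sample`` indicates an inconsistent pipeline state.
    """
    height, width = len(panel), panel.max_length
    grid = np.zeros((height, width), dtype=float)
    clipped = 0
    for i, entry in enumerate(panel.entries):
        try:
            raw = sample.loc[list(entry.genes)].to_numpy(dtype=float)
        except KeyError as exc:
            raise RuntimeError(
                f"internal inconsistency: pathway {entry.pathway_id} references "
                f"a gene absent from the sample vector ({exc}); was the panel "
                "pruned against this matrix?"
            ) from exc
        scaled = scaler.scale(raw)
        clipped += int(((raw < scaler.v_min) | (raw > scaler.v_max)).sum())
        grid[i, : len(entry.genes)] = scaled
    if clipped:
        logger.info(
            "build_image: sample %s: %d pixel(s) clipped to the scaler range",
            sample.name, clipped,
        )
    return SampleImage(sample_id=str(sample.name), grid=grid)


def build_images(
    matrix: pd.DataFrame, panel: PathwayPanel, scaler: IntensityScaler
) -> list[SampleImage]:
    """Build one image per column of a normalized gene x sample matrix."""
    return [build_image(matrix[c], panel, scaler) for c in matrix.columns]


def export_png(image: SampleImage, path) -> None:
    """Write an 8-bit RGB PNG: R = round(value*255), G = B = 0."""
    red = np.rint(image.grid * 255).astype(np.uint8)
    rgb = np.zeros((*red.shape, 3), dtype=np.uint8)
    rgb[:, :, 0] = red
    Image.fromarray(rgb, mode="RGB").save(path, format="PNG")


def save_image_container(
    path,
    images: list[SampleImage],
    labels: pd.Series,
    scaler: IntensityScaler,
    panel_checksum: str | None = None,
) -> None:
    """Persist an image batch to HDF5 (datasets images / sample_ids / labels)."""
    stack = np.stack([im.grid for im in images])
    ids = [im.sample_id for im in images]
    with h5py.File(path, "w") as f:
        f.create_dataset("images", data=stack)
        f.create_dataset("sample_ids", data=np.array(ids, dtype="S"))
        f.create_dataset(
            "labels", data=labels.reindex(ids).to_numpy(dtype=np.int8)
        )
        f.attrs["v_min"] = scaler.v_min
        f.attrs["v_max"] = scaler.v_max
        if panel_checksum is not None:
            f.attrs["panel_checksum"] = panel_checksum


def load_image_container(path):
    with h5py.File(path, "r") as f:
        stack = f["images"][()]
        ids = [s.decode() for s in f["sample_ids"][()]]
        labels = pd.Series(f["labels"][()], index=ids)
        scaler = IntensityScaler(float(f.attrs["v_min"]), float(f.attrs["v_max"]))
    images = [SampleImage(sid, grid) for sid, grid in zip(ids, stack)]
    return images, labels, scaler
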