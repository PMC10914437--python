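"""Reading and pairing of spatial-transcriptomics tables and IF images.

Conventions (fixed across the package):

* pixel coordinates are 0-based on an integer pixel-center grid;
* a crop of size H centered on (cx, cy) covers the half-open window
  ``[cx - H//2, cx + (H+1)//2) x [cy - H//2, cy + (H+1)//2)`` — a transcript
  exactly on the right/bottom edge is excluded;
* transcripts with a missing/empty cell assignment are dropped at load time;
* per-cell expression is the spatial sum of the cell's sparse transcript
  array over its crop window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "TranscriptTable",
    "Sparse3D",
    "CellCrop",
    "ExpressionMatrix",
    "read_transcripts",
    "crop_cell_array",
    "sum_expression",
    "crop_cell_image",
    "select_subtypes",
    "load_fixture",
]


@dataclass
class TranscriptTable:
    """Per-transcript records with genes resolved to panel indices."""

    gene: np.ndarray      # (m,) panel indices
    x: np.ndarray         # (m,) pixels
    y: np.ndarray         # (m,) pixels
    cell_id: np.ndarray   # (m,) strings
    fov: np.ndarray       # (m,)
    panel: list[str]

    def __len__(self) -> int:
        return len(self.gene)


@dataclass
class Sparse3D:
    """COO-style sparse gene x H x W transcript-count array for one cell."""

    gene: np.ndarray
    row: np.ndarray       # y within crop
    col: np.ndarray       # x within crop
    count: np.ndarray
    shape: tuple[int, int, int]

    def todense(self) -> np.ndarray:
        out = np.zeros(self.shape, dtype=np.int64)
        np.add.at(out, (self.gene, self.row, self.col), self.count)
        return out

    @property
    def total(self) -> int:
        return int(self.count.sum())


@dataclass
class CellCrop:
    """One paired record: expression vector + 2-channel crop + annotations."""

    cell_id: str
    expr: np.ndarray          # (p,)
    image: np.ndarray         # (2, H, W), channel order (nuclear, marker)
    label: int                # 0 normal / 1 tumor
    subtype: str
    padded: bool = False
    clamped: bool = False


@dataclass
class ExpressionMatrix:
    """Population expression matrix with annotations.

    ``real_valued`` is False for raw (nonnegative count) data and True for
    post-edit matrices, which may contain negative entries.
    """

    G: np.ndarray             # (n, p)
    labels: np.ndarray        # (n,)
    subtypes: np.ndarray      # (n,) strings
    panel: list[str]
    cell_ids: np.ndarray | None = None
    real_valued: bool = False

    def __post_init__(self):
        self.G = np.asarray(self.G, dtype=np.float64)
        if not self.real_valued and self.G.size and self.G.min() < 0:
            raise ValueError("count-state expression matrix has negative entries")

    @property
    def n(self) -> int:
        return self.G.shape[0]

    @property
    def p(self) -> int:
        return self.G.shape[1]

    def population(self, label: int) -> np.ndarray:
        return self.G[self.labels == label]


def read_transcripts(path, panel: list[str]) -> TranscriptTable:
    """Load a CosMx-dialect transcript table (CSV or Parquet).

    Columns: ``fov, cell_ID, target, x_global_px, y_global_px``.  Unknown gene
    names raise; transcripts with missing/empty/0 cell assignment are dropped.
    """
    path = Path(path)
    df = pd.read_parquet(path) if path.suffix == ".parquet" else pd.read_csv(path)
    required = {"fov", "cell_ID", "target", "x_global_px", "y_global_px"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"transcript table missing columns: {sorted(missing)}")

    cid = df["cell_ID"].astype(str)
    keep = cid.notna() & ~cid.isin(["", "0", "nan", "None"])
    df = df[keep]

    lookup = {g: i for i, g in enumerate(panel)}
    unknown = sorted(set(df["target"]) - set(lookup))
    if unknown:
        raise ValueError(f"unknown gene names in transcript table: {unknown}")
    xy = df[["x_global_px", "y_global_px"]].to_numpy(dtype=np.float64)
    if not np.isfinite(xy).all():
        raise ValueError("non-finite transcript coordinates")
    return TranscriptTable(
        gene=df["target"].map(lookup).to_numpy(dtype=np.intp),
        x=df["x_global_px"].to_numpy(dtype=np.float64),
        y=df["y_global_px"].to_numpy(dtype=np.float64),
        cell_id=df["cell_ID"].astype(str).to_numpy(),
        fov=df["fov"].to_numpy(),
        panel=list(panel),
    )


def _window(center: float, size: int) -> tuple[int, int]:
    c = int(round(center))
    return c - size // 2, c - size // 2 + size


def crop_cell_array(table: TranscriptTable, cell, crop: int) -> Sparse3D:
    """Sparse gene x crop x crop transcript array for one cell.

    ``cell`` needs attributes/keys ``cell_id``, ``cx``, ``cy``.  Only this
    cell's transcripts inside the half-open window count; others are excluded.
    """
    if crop <= 0:
        raise ValueError("crop size must be positive")
    cell_id, cx, cy = _cell_fields(cell)
    sel = table.cell_id == cell_id
    x, y, g = table.x[sel], table.y[sel], table.gene[sel]
    x0, x1 = _window(cx, crop)
    y0, y1 = _window(cy, crop)
    inside = (x >= x0) & (x < x1) & (y >= y0) & (y < y1)
    cols = np.floor(x[inside]).astype(np.intp) - x0
    rows = np.floor(y[inside]).astype(np.intp) - y0
    genes = g[inside]
    return Sparse3D(gene=genes, row=rows, col=cols,
                    count=np.ones(len(genes), dtype=np.int64),
                    shape=(len(table.panel), crop, crop))


def sum_expression(arr: Sparse3D) -> np.ndarray:
    """Sum the sparse 3-D array over its spatial dimensions -> length-p vector."""
    out = np.zeros(arr.shape[0], dtype=np.int64)
    np.add.at(out, arr.gene, arr.count)
    return out


def crop_cell_image(image: np.ndarray, cell, crop: int,
                    channels: tuple[int, int] = (0, 1),
                    scale: tuple[float, float] | None = None):
    """Center-crop a 2-channel patch from a (C, H, W) slide image.

    Returns ``(patch, padded, clamped)``.  A centroid outside the slide is
    clamped so the window fits (``clamped`` flag); a window partially outside
    is zero-padded (``padded`` flag).  Values are affinely rescaled to [0, 1]
    using ``scale=(lo, hi)``; when None, lo = min and hi = 99.9th percentile
    of the slide (robust to hot pixels), computed per call.
    """
    image = np.asarray(image)
    for ch in channels:
        if ch >= image.shape[0]:
            raise ValueError(f"requested channel {ch} not in image with {image.shape[0]} channels")
    _, H, W = image.shape[0], image.shape[-2], image.shape[-1]
    cell_id, cx, cy = _cell_fields(cell)

    clamped = False
    if not (0 <= cx < W and 0 <= cy < H):
        cx = float(np.clip(cx, crop // 2, max(W - (crop + 1) // 2, crop // 2)))
        cy = float(np.clip(cy, crop // 2, max(H - (crop + 1) // 2, crop // 2)))
        clamped = True
    x0, x1 = _window(cx, crop)
    y0, y1 = _window(cy, crop)

    patch = np.zeros((len(channels), crop, crop), dtype=np.float64)
    sx0, sx1 = max(x0, 0), min(x1, W)
    sy0, sy1 = max(y0, 0), min(y1, H)
    padded = (sx0 != x0) or (sx1 != x1) or (sy0 != y0) or (sy1 != y1)
    if sx1 > sx0 and sy1 > sy0:
        sub = image[list(channels), sy0:sy1, sx0:sx1].astype(np.float64)
        patch[:, sy0 - y0:sy1 - y0, sx0 - x0:sx1 - x0] = sub
    if scale is None:
        lo = float(image[list(channels)].min())
        hi = float(np.percentile(image[list(channels)], 99.9))
    else:
        lo, hi = scale
    if hi > lo:
        np.clip((patch - lo) / (hi - lo), 0.0, 1.0, out=patch)
    return patch, padded, clamped


def _cell_fields(cell):
    if isinstance(cell, dict):
        return str(cell["cell_ID"]), float(cell["cx"]), float(cell["cy"])
    if isinstance(cell, pd.Series):
        return str(cell["cell_ID"]), float(cell["cx"]), float(cell["cy"])
    return str(cell.cell_id), float(cell.cx), float(cell.cy)


def select_subtypes(em: ExpressionMatrix, normal_set, tumor_set):
    """Keep cells whose subtype is in either set; relabel 0/1 accordingly.

    Returns ``(filtered ExpressionMatrix, retained_fraction)``.  The sets must
    be disjoint and the result nonempty (downstream second moments are
    undefined on an empty population).  Idempotent.
    """
    normal_set, tumor_set = set(normal_set), set(tumor_set)
    overlap = normal_set & tumor_set
    if overlap:
        raise ValueError(f"subtypes present in both sets: {sorted(overlap)}")
    is_n = np.isin(em.subtypes, sorted(normal_set))
    is_t = np.isin(em.subtypes, sorted(tumor_set))
    keep = is_n | is_t
    if not keep.any():
        raise ValueError("subtype selection retained no cells")
    labels = np.where(is_t[keep], 1, 0)
    out = ExpressionMatrix(
        G=em.G[keep], labels=labels, subtypes=em.subtypes[keep],
        panel=list(em.panel),
        cell_ids=None if em.cell_ids is None else em.cell_ids[keep],
        real_valued=em.real_valued,
    )
    return out, float(keep.mean())


def load_fixture(fixture_dir) -> tuple[list[CellCrop], ExpressionMatrix]:
    """Load a written fixture back into paired records via crop-and-sum."""
    d = Path(fixture_dir)
    with open(d / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    panel = manifest["panel"]
    crop = manifest["crop_size"]
    scale_cfg = manifest["intensity_scale"]
    meta = pd.read_csv(d / "metadata.csv", dtype={"cell_ID": str})

    crops: list[CellCrop] = []
    exprs, labels, subtypes, ids = [], [], [], []
    for slide, label in (("normal", 0), ("tumor", 1)):
        rows = meta[meta["slide"] == slide]
        if rows.empty:
            continue
        table = read_transcripts(d / manifest["files"][f"transcripts_{slide}"], panel)
        raw = tifffile.imread(d / manifest["files"][f"image_{slide}"]).astype(np.float64)
        raw /= scale_cfg["raw_max"]
        lo, hi = scale_cfg["lo"], scale_cfg["hi"]
        for _, cell in rows.iterrows():
            arr = crop_cell_array(table, cell, crop)
            expr = sum_expression(arr)
            patch, padded, clamped = crop_cell_image(raw, cell, crop, scale=(lo, hi))
            crops.append(CellCrop(cell_id=str(cell["cell_ID"]), expr=expr,
                                  image=patch, label=label,
                                  subtype=str(cell["subtype"]),
                                  padded=padded, clamped=clamped))
            exprs.append(expr)
            labels.append(label)
            subtypes.append(str(cell["subtype"]))
            ids.append(str(cell["cell_ID"]))
    em = ExpressionMatrix(
        G=np.array(exprs, dtype=np.float64) if exprs else np.zeros((0, len(panel))),
        labels=np.array(labels, dtype=np.int64),
        subtypes=np.array(subtypes), panel=list(panel),
        cell_ids=np.array(ids),
    )
    return crops, em
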