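"""Synthetic CosMx-like paired spatial-transcriptomics + immunofluorescence data.

The generator emulates the structure the editing pipeline relies on, at desk
scale and with known ground truth:

* two cell populations ("normal" and "tumor" slides) whose gene-expression
  vectors have distinct second-moment structure;
* a small set of *driver* genes whose summed expression causally controls the
  paired two-channel cell image — nuclear area (DAPI-role channel) and mean
  membrane-marker intensity (CD298/B2M-role channel) are monotone functions of
  the driver sum;
* subtype annotations per cell, so subtype selection is exercisable.

Expression link
---------------
Targets are *scaled second-moment* matrices sigma = E[g g^T] (uncentered).
A draw is ``g = max(mu + L z, 0)`` with ``mu = mean_fraction * sqrt(diag(sigma))``
and ``L L^T = sigma - mu mu^T``: a truncated-at-zero shifted Gaussian.  The
truncation at zero biases the realized second moment slightly below the
target; with the default ``mean_fraction = 0.8`` the truncated mass per gene
is about 9% and the bias stays within a few percent (the closed-form moments
of the truncated normal give the exact realized values for diagonal targets).
Real platforms produce integer counts; `simulate_dataset` therefore rounds
expression to integer counts before scattering transcripts, while the
continuous draw remains available for moment-level analyses.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "SimConfig",
    "SyntheticDataset",
    "simulate_expression",
    "render_cell_image",
    "simulate_dataset",
    "write_fixture",
]

_QUANT = 65535  # images live on the 16-bit grid so TIFF round-trips are exact


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic paired dataset.

    ``sigma0``/``sigma1`` are the target p x p scaled second-moment matrices of
    the two populations (symmetric PSD).  ``nucleus_area_map`` holds
    ``(slope, intercept, min_area, max_area_frac)`` mapping the driver-gene sum
    s to an expected nucleus area ``clip(slope*s + intercept, min_area,
    max_area_frac * image_size**2)`` in pixels^2.  ``marker_gain`` maps s to the
    mean marker-channel intensity ``clip(marker_gain * s, 0, 1)``.
    """

    p: int
    n0: int
    n1: int
    driver_genes: tuple[int, ...]
    sigma0: np.ndarray
    sigma1: np.ndarray
    image_size: int = 32
    nucleus_area_map: tuple[float, float, float, float] = (8.0, 30.0, 20.0, 0.35)
    marker_gain: float = 0.05
    mean_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.p < 2:
            raise ValueError("panel size p must be >= 2")
        if self.n0 < 1 or self.n1 < 1:
            raise ValueError("populations must have at least one cell")
        drivers = tuple(int(g) for g in self.driver_genes)
        if not drivers or not all(0 <= g < self.p for g in drivers):
            raise ValueError("driver_genes must be a nonempty subset of 0..p-1")
        object.__setattr__(self, "driver_genes", drivers)
        for name in ("sigma0", "sigma1"):
            sig = np.asarray(getattr(self, name), dtype=np.float64)
            if sig.shape != (self.p, self.p):
                raise ValueError(f"{name} must be {self.p}x{self.p}")
            object.__setattr__(self, name, sig)

    def sigma(self, population: int) -> np.ndarray:
        return self.sigma0 if population == 0 else self.sigma1

    @classmethod
    def default(cls, p: int = 30, n0: int = 2000, n1: int = 2000,
                image_size: int = 32, seed: int = 0) -> "SimConfig":
        """Default study conditions: two drivers (genes 0 and 1) that are low
        in the normal population and strongly up-regulated plus correlated in
        the tumor population, a couple of down-regulated genes, and mildly
        structured background covariance distinct per population."""
        if p < 4:
            raise ValueError("default config needs p >= 4")
        alpha = 0.8
        rng = np.random.default_rng(20240210)  # structural constants, not per-run noise

        def build(mu: np.ndarray, driver_rho: float, uvec: np.ndarray) -> np.ndarray:
            cdiag = mu**2 * (1.0 / alpha**2 - 1.0)
            d = np.sqrt(cdiag)
            corr = 0.85 * np.eye(p) + 0.15 * np.outer(uvec, uvec)
            corr[0, 1] = corr[1, 0] = driver_rho
            cov = np.outer(d, d) * corr
            # guard: clip tiny negative eigenvalues introduced by the patch
            w, v = np.linalg.eigh(cov)
            cov = (v * np.clip(w, 0.0, None)) @ v.T
            return cov + np.outer(mu, mu)

        base = rng.uniform(1.0, 4.0, size=p)
        mu0 = base.copy()
        mu0[0] = mu0[1] = 2.0       # drivers low in normal
        mu0[2] = 4.0                # "APOA1"-role gene high in normal
        mu0[3] = 4.0                # "TTR"-role gene high in normal
        mu1 = base.copy()
        mu1[0] = mu1[1] = 8.0       # drivers up-regulated in tumor
        mu1[2] = 1.0
        mu1[3] = 1.0
        u0 = rng.normal(size=p)
        u0 /= np.linalg.norm(u0)
        u1 = rng.normal(size=p)
        u1 /= np.linalg.norm(u1)
        return cls(p=p, n0=n0, n1=n1, driver_genes=(0, 1),
                   sigma0=build(mu0, 0.2, u0), sigma1=build(mu1, 0.6, u1),
                   image_size=image_size, mean_fraction=alpha, seed=seed)


def _check_psd(sigma: np.ndarray, name: str) -> np.ndarray:
    sym_err = np.abs(sigma - sigma.T).max()
    if sym_err > 1e-8 * max(1.0, np.abs(sigma).max()):
        raise ValueError(f"{name} is not symmetric (max asymmetry {sym_err:.3g})")
    w = np.linalg.eigvalsh(sigma)
    if w.min() < -1e-10 * max(w.max(), 1.0):
        raise ValueError(
            f"{name} is not positive semidefinite: most negative eigenvalue {w.min():.6g}"
        )
    return sigma


def _link_parameters(sigma: np.ndarray, mean_fraction: float):
    """Split a target second moment into (mu, factor L) for the truncated link.

    ``mu = f * sqrt(diag(sigma))`` requires ``f**2 * s^T sigma^+ s <= 1``
    (s = sqrt(diag)) for ``sigma - mu mu^T`` to stay PSD; the requested mean
    fraction is capped at that feasibility bound, so any PSD target is valid
    at the cost of heavier truncation (larger realized-moment bias).
    """
    s = np.sqrt(np.diag(sigma))
    x, *_ = np.linalg.lstsq(sigma, s, rcond=None)
    t = float(s @ x)
    f = mean_fraction
    if t > 0:
        f = min(f, np.sqrt(0.995 / t))
    mu = f * s
    cov = sigma - np.outer(mu, mu)
    w, v = np.linalg.eigh(cov)
    if w.min() < -1e-8 * max(w.max(), 1.0):
        raise ValueError(
            "sigma - mu mu^T is not PSD; lower mean_fraction "
            f"(most negative eigenvalue {w.min():.6g})"
        )
    L = v * np.sqrt(np.clip(w, 0.0, None))
    return mu, L


def simulate_expression(cfg: SimConfig, population: int) -> np.ndarray:
    """Draw the expression matrix (n x p, nonnegative, continuous) of one
    population.  Deterministic in ``(cfg.seed, population)``."""
    if population not in (0, 1):
        raise ValueError("population must be 0 or 1")
    sigma = _check_psd(cfg.sigma(population), f"sigma{population}")
    mu, L = _link_parameters(sigma, cfg.mean_fraction)
    n = cfg.n0 if population == 0 else cfg.n1
    rng = np.random.default_rng([cfg.seed, 101 + population])
    z = rng.standard_normal(size=(n, cfg.p))
    return np.maximum(mu + z @ L.T, 0.0)


def _ellipse_mask(size: int, area: float, ratio: float) -> np.ndarray:
    """Centered axis-aligned ellipse of the given area; ``ratio`` is the
    axis-ratio jitter (1 = circle).  Area is preserved under the jitter."""
    r = np.sqrt(area / np.pi)
    a, b = r * np.sqrt(ratio), r / np.sqrt(ratio)
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    return ((xx - c) / a) ** 2 + ((yy - c) / b) ** 2 <= 1.0


def nucleus_area(cfg: SimConfig, driver_sum: float) -> float:
    """Expected nucleus area (pixels^2) for a driver-gene sum."""
    slope, intercept, min_area, max_frac = cfg.nucleus_area_map
    return float(np.clip(slope * driver_sum + intercept,
                         min_area, max_frac * cfg.image_size**2))


def render_cell_image(expr: np.ndarray, cfg: SimConfig,
                      rng: np.random.Generator,
                      return_masks: bool = False):
    """Render the paired 2-channel crop for one expression vector.

    Channel 0 (nuclear): centered ellipse whose area follows
    ``nucleus_area(cfg, driver_sum)`` with bounded noise.  Channel 1 (marker):
    membrane ring around the nucleus with mean intensity
    ``clip(marker_gain * driver_sum, 0, 1)`` plus bounded noise.  Output is
    float in [0,1], quantized to the 16-bit grid so TIFF round-trips are exact.
    Only driver genes influence the image.
    """
    expr = np.asarray(expr, dtype=np.float64)
    if expr.shape != (cfg.p,):
        raise ValueError(f"expression vector must have length {cfg.p}")
    s = float(expr[list(cfg.driver_genes)].sum())
    size = cfg.image_size
    area = nucleus_area(cfg, s)
    ratio = rng.uniform(0.85, 1.18)
    nuc = _ellipse_mask(size, area, ratio)
    ring_outer = _ellipse_mask(size, np.pi * (np.sqrt(area / np.pi) + 3.0) ** 2, ratio)
    ring = ring_outer & ~nuc

    img = np.zeros((2, size, size))
    img[0] = 0.015 + rng.uniform(-0.01, 0.01, size=(size, size))
    img[0][nuc] = 0.85 + rng.uniform(-0.05, 0.05, size=int(nuc.sum()))
    marker = float(np.clip(cfg.marker_gain * s, 0.0, 1.0))
    img[1] = 0.005 + rng.uniform(-0.005, 0.005, size=(size, size))
    img[1][ring] = marker + rng.uniform(-0.02, 0.02, size=int(ring.sum()))
    img = np.round(np.clip(img, 0.0, 1.0) * _QUANT) / _QUANT
    if return_masks:
        return img, nuc, ring
    return img


@dataclass
class SyntheticDataset:
    """In-memory paired dataset: integer counts, rendered crops, annotations."""

    cfg: SimConfig
    counts: np.ndarray          # (n, p) integer transcript counts
    expr: np.ndarray            # (n, p) continuous pre-rounding draw
    images: np.ndarray          # (n, 2, S, S) in [0, 1]
    labels: np.ndarray          # (n,) 0 normal / 1 tumor
    subtypes: np.ndarray        # (n,) strings
    cell_ids: np.ndarray        # (n,) strings
    centroids: np.ndarray       # (n, 2) integer (cx, cy) in the slide image
    panel: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.labels)


_SUBTYPES = {0: ("Hep.1", "Hep.3", "Hep.4"), 1: ("Tumor.1", "Tumor.2")}


def simulate_dataset(cfg: SimConfig) -> SyntheticDataset:
    """Full fixture: expression (rounded to counts), images, labels, layout.

    Cells of each population are placed on a non-overlapping grid of
    ``image_size`` pitch on that population's slide, so every crop window is
    disjoint and crop-and-sum recovers each cell's counts exactly.
    """
    panel = [f"g{i:03d}" for i in range(cfg.p)]
    parts = []
    for pop in (0, 1):
        cont = simulate_expression(cfg, pop)
        counts = np.round(cont).astype(np.int64)
        n = counts.shape[0]
        rng = np.random.default_rng([cfg.seed, 211 + pop])
        imgs = np.stack([render_cell_image(counts[i].astype(float), cfg, rng)
                         for i in range(n)])
        sub = rng.choice(_SUBTYPES[pop], size=n)
        ncol = int(np.ceil(np.sqrt(n)))
        idx = np.arange(n)
        s = cfg.image_size
        cx = (idx % ncol) * s + s // 2
        cy = (idx // ncol) * s + s // 2
        ids = np.array([f"c{pop}_{i:05d}" for i in range(n)])
        parts.append((counts, cont, imgs, np.full(n, pop), sub, ids,
                      np.stack([cx, cy], axis=1)))
    return SyntheticDataset(
        cfg=cfg,
        counts=np.concatenate([p[0] for p in parts]),
        expr=np.concatenate([p[1] for p in parts]),
        images=np.concatenate([p[2] for p in parts]),
        labels=np.concatenate([p[3] for p in parts]),
        subtypes=np.concatenate([p[4] for p in parts]),
        cell_ids=np.concatenate([p[5] for p in parts]),
        centroids=np.concatenate([p[6] for p in parts]),
        panel=panel,
    )


def _disc_offsets(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    keep = xx**2 + yy**2 <= radius**2
    return np.stack([xx[keep], yy[keep]], axis=1)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_fixture(dataset: SyntheticDataset, out_dir, overwrite: bool = False,
                  transcript_format: str = "csv") -> dict:
    """Write the dataset as on-disk fixture files and return the manifest.

    Layout: per-slide transcript table (CosMx tx dialect:
    ``fov,cell_ID,target,x_global_px,y_global_px``), a shared per-cell
    metadata CSV (``cell_ID,slide,subtype,cx,cy``), one 2-channel 16-bit TIFF
    per slide, and a YAML manifest with per-file SHA-256 checksums and the
    intensity scale.  Transcripts are scattered uniformly on the integer pixel
    disc of radius ``image_size//2 - 2`` around each centroid, strictly inside
    the cell's crop window.
    """
    from pathlib import Path

    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} exists and is not empty; pass overwrite=True")
    out.mkdir(parents=True, exist_ok=True)

    cfg = dataset.cfg
    s = cfg.image_size
    offsets = _disc_offsets(s // 2 - 2)
    rng = np.random.default_rng([cfg.seed, 307])
    slide_names = {0: "normal", 1: "tumor"}
    files: dict[str, str] = {}

    meta = pd.DataFrame({
        "cell_ID": dataset.cell_ids,
        "slide": [slide_names[int(l)] for l in dataset.labels],
        "subtype": dataset.subtypes,
        "cx": dataset.centroids[:, 0],
        "cy": dataset.centroids[:, 1],
    })
    meta_path = out / "metadata.csv"
    meta.to_csv(meta_path, index=False)
    files["metadata"] = meta_path.name

    for pop, slide in slide_names.items():
        sel = np.flatnonzero(dataset.labels == pop)
        rows = {"fov": [], "cell_ID": [], "target": [],
                "x_global_px": [], "y_global_px": []}
        for i in sel:
            counts = dataset.counts[i]
            total = int(counts.sum())
            if total:
                picks = offsets[rng.integers(0, len(offsets), size=total)]
                genes = np.repeat(np.arange(cfg.p), counts)
                rows["fov"].extend([0] * total)
                rows["cell_ID"].extend([dataset.cell_ids[i]] * total)
                rows["target"].extend(dataset.panel[g] for g in genes)
                rows["x_global_px"].extend(dataset.centroids[i, 0] + picks[:, 0])
                rows["y_global_px"].extend(dataset.centroids[i, 1] + picks[:, 1])
        tx = pd.DataFrame(rows)
        if transcript_format == "parquet":
            tx_path = out / f"tx_{slide}.parquet"
            tx.to_parquet(tx_path, index=False)
        else:
            tx_path = out / f"tx_{slide}.csv"
            tx.to_csv(tx_path, index=False)
        files[f"transcripts_{slide}"] = tx_path.name

        if len(sel):
            ncol = int(np.ceil(np.sqrt(len(sel))))
            nrow = int(np.ceil(len(sel) / ncol))
            canvas = np.zeros((2, nrow * s, ncol * s))
            for i in sel:
                cx, cy = dataset.centroids[i]
                canvas[:, cy - s // 2: cy + s // 2, cx - s // 2: cx + s // 2] = dataset.images[i]
        else:
            canvas = np.zeros((2, s, s))
        img_path = out / f"image_{slide}.tiff"
        tifffile.imwrite(img_path, np.round(canvas * _QUANT).astype(np.uint16))
        files[f"image_{slide}"] = img_path.name

    manifest = {
        "panel": list(dataset.panel),
        "crop_size": s,
        "channels": {"nuclear": 0, "marker": 1},
        "intensity_scale": {"lo": 0.0, "hi": 1.0, "raw_max": _QUANT},
        "n_cells": int(dataset.n),
        "driver_genes": list(cfg.driver_genes),
        "seed": int(cfg.seed),
        "files": files,
    }
    manifest_path = out / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    manifest["checksums"] = {name: _sha256(out / fname) for name, fname in files.items()}
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
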