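"""Population-level expression editing by second-moment matching.

Because imaging-based ST slides carry no one-to-one correspondence between
individual normal and tumor cells, editing is defined collectively: the
expression matrix ``G_i`` (n_i x p) of the source population is mapped by a
fixed linear transform so that its scaled second-moment matrix (SCM)

    S_i = (1/n_i) G_i^T G_i = O_i diag(lam_i) O_i^T

becomes the target population's ``S_j``.  With eigenvalues sorted
nonincreasing, the full-mode transform is

    G_i' = G_i . O_i . diag(sqrt(lam_j / lam_i)) . O_j^T

which satisfies (1/n_i) G_i'^T G_i' = S_j exactly in the full-rank case:
the inner rotation whitens in the source eigenbasis, the scale matches the
target spectrum, the outer rotation re-colors into the target eigenbasis.

Modes
-----
full     match the whole spectrum (exact SCM matching).
leading  scale only the largest eigenvalue (scale vector (sqrt(lam_j[0] /
         lam_i[0]), 1, ..., 1)) inside the same rotation sandwich — the
         leading eigenvalue dominates and trailing eigenvalues fluctuate.

A gene-restriction step can freeze all columns outside an ``edit_genes`` set,
narrowing the edit to the genes of interest (e.g. the HLA-A/B2M drivers); the
frozen columns are bit-identical to the input and exact SCM matching is then
only approximate, with the achieved residual recorded in the provenance.

Edited matrices are real-valued (possibly negative): clipping would break the
exact-matching contract, and the generator conditioning accepts real vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .st_io import ExpressionMatrix

__all__ = [
    "ScmDecomposition",
    "EditSpec",
    "compute_scm",
    "eigendecompose",
    "match_transform",
    "restrict_edit",
    "edit_population",
]


@dataclass
class ScmDecomposition:
    """Eigendecomposition of a population SCM: ``scm = O diag(lam) O^T``.

    Columns of ``O`` are orthonormal; ``lam`` is sorted nonincreasing and
    nonnegative; ``n`` is the population size behind the SCM.
    """

    O: np.ndarray
    lam: np.ndarray
    n: int

    def reconstruct(self) -> np.ndarray:
        return (self.O * self.lam) @ self.O.T


@dataclass
class EditSpec:
    """What to edit: mode in {"full", "leading"}; ``edit_genes`` (panel
    indices) is the set of genes ALLOWED TO CHANGE (None = all); source and
    target are population labels."""

    mode: str = "full"
    edit_genes: list[int] | None = None
    source: int = 1
    target: int = 0

    def __post_init__(self):
        if self.mode not in ("full", "leading"):
            raise ValueError(f"unknown edit mode: {self.mode!r}")


def compute_scm(G) -> np.ndarray:
    """Scaled (uncentered) second-moment matrix (1/n) G^T G."""
    if isinstance(G, ExpressionMatrix):
        G = G.G
    G = np.asarray(G, dtype=np.float64)
    if G.ndim != 2 or G.shape[0] == 0:
        raise ValueError("expression matrix must be 2-D with n >= 1 rows")
    scm = G.T @ G / G.shape[0]
    return (scm + scm.T) / 2.0


def eigendecompose(scm: np.ndarray, n: int = 0) -> ScmDecomposition:
    """Eigendecomposition with deterministic conventions.

    Eigenvalues sorted nonincreasing (ties keep ascending-order output of the
    symmetric solver, i.e. a fixed order); each eigenvector's
    largest-magnitude entry (lowest index on ties) is made positive.  Small
    negative eigenvalues are clipped to zero; materially negative ones raise.
    """
    scm = np.asarray(scm, dtype=np.float64)
    asym = np.abs(scm - scm.T).max() if scm.size else 0.0
    if asym > 1e-8 * max(1.0, np.abs(scm).max()):
        raise ValueError(f"matrix is not symmetric (max asymmetry {asym:.3g})")
    w, v = np.linalg.eigh((scm + scm.T) / 2.0)
    order = np.argsort(-w, kind="stable")
    w, v = w[order], v[:, order]
    top = max(w[0], 0.0)
    if w[-1] < -1e-10 * max(top, 1.0):
        raise ValueError(f"matrix has negative eigenvalue {w[-1]:.6g}")
    w = np.clip(w, 0.0, None)
    # sign convention: largest-|entry| of each eigenvector positive
    idx = np.argmax(np.abs(v), axis=0)
    signs = np.sign(v[idx, np.arange(v.shape[1])])
    signs[signs == 0] = 1.0
    v = v * signs
    return ScmDecomposition(O=v, lam=w, n=int(n))


def _scale_vector(lam_i: np.ndarray, lam_j: np.ndarray, mode: str) -> np.ndarray:
    if lam_i[0] <= 0.0:
        raise ValueError("source population SCM is zero; nothing to match")
    tol = 1e-12 * lam_i[0]
    if mode == "full":
        scale = np.zeros_like(lam_i)
        nz = lam_i > tol
        scale[nz] = np.sqrt(lam_j[nz] / lam_i[nz])  # pseudo-inverse rule on null space
    else:  # leading
        scale = np.ones_like(lam_i)
        scale[0] = np.sqrt(lam_j[0] / lam_i[0])
    return scale


def match_transform(G_i: np.ndarray, dec_i: ScmDecomposition,
                    dec_j: ScmDecomposition, spec: EditSpec) -> np.ndarray:
    """Apply the SCM-matching linear map rowwise: ``G_i' = G_i T`` with
    ``T = O_i diag(scale) O_j^T``."""
    G_i = np.asarray(G_i, dtype=np.float64)
    if dec_i.O.shape != dec_j.O.shape:
        raise ValueError("decompositions come from different panel sizes")
    if G_i.shape[1] != dec_i.O.shape[0]:
        raise ValueError("matrix width does not match decomposition")
    if np.array_equal(dec_i.O, dec_j.O) and np.array_equal(dec_i.lam, dec_j.lam):
        # self-edit: scale is all ones and O_i O_i^T = I, so the map is the
        # identity; return the input bit-exactly rather than multiplying it out
        if dec_i.lam[0] <= 0.0:
            raise ValueError("source population SCM is zero; nothing to match")
        return G_i.copy()
    scale = _scale_vector(dec_i.lam, dec_j.lam, spec.mode)
    T = (dec_i.O * scale) @ dec_j.O.T
    return G_i @ T


def restrict_edit(G_i: np.ndarray, G_i_edited: np.ndarray, edit_genes) -> np.ndarray:
    """Take edited values on ``edit_genes`` columns, original values elsewhere."""
    G_i = np.asarray(G_i, dtype=np.float64)
    G_i_edited = np.asarray(G_i_edited, dtype=np.float64)
    if G_i.shape != G_i_edited.shape:
        raise ValueError("original and edited matrices differ in shape")
    edit_genes = [] if edit_genes is None else list(edit_genes)
    if any(g < 0 or g >= G_i.shape[1] for g in edit_genes):
        raise ValueError("edit_genes outside panel")
    out = G_i.copy()
    if edit_genes:
        out[:, edit_genes] = G_i_edited[:, edit_genes]
    return out


@dataclass
class EditResult:
    edited: ExpressionMatrix
    provenance: dict = field(default_factory=dict)


def edit_population(em: ExpressionMatrix, spec: EditSpec) -> EditResult:
    """End-to-end edit of the source population toward the target population.

    Computes both SCMs, eigendecomposes, applies the matching transform (and
    the optional gene restriction), and returns the edited source-population
    matrix together with a provenance record: mode, edited genes, eigenvalue
    ratios and the achieved SCM-match residual (relative Frobenius error
    against the target SCM).
    """
    G_src = em.population(spec.source)
    G_tgt = em.population(spec.target)
    if G_src.shape[0] == 0 or G_tgt.shape[0] == 0:
        raise ValueError("both populations must be present in the dataset")
    dec_i = eigendecompose(compute_scm(G_src), n=G_src.shape[0])
    dec_j = eigendecompose(compute_scm(G_tgt), n=G_tgt.shape[0])
    edited_full = match_transform(G_src, dec_i, dec_j, spec)
    if spec.edit_genes is not None:
        edited = restrict_edit(G_src, edited_full, spec.edit_genes)
    else:
        edited = edited_full
    scm_out = compute_scm(edited)
    scm_tgt = dec_j.reconstruct()
    residual = np.linalg.norm(scm_out - scm_tgt) / max(np.linalg.norm(scm_tgt), 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(dec_i.lam > 0, dec_j.lam / dec_i.lam, np.inf)
    src_mask = em.labels == spec.source
    G_all = em.G.copy()
    G_all[src_mask] = edited
    out = ExpressionMatrix(G=G_all, labels=em.labels.copy(),
                           subtypes=em.subtypes.copy(), panel=list(em.panel),
                           cell_ids=None if em.cell_ids is None else em.cell_ids.copy(),
                           real_valued=True)
    prov = {
        "mode": spec.mode,
        "source": int(spec.source),
        "target": int(spec.target),
        "edit_genes": None if spec.edit_genes is None else [int(g) for g in spec.edit_genes],
        "eigenvalue_ratio_leading": float(ratios[0]),
        "eigenvalue_ratios": [float(r) for r in ratios],
        "scm_match_residual": float(residual),
        "n_source": int(G_src.shape[0]),
        "n_target": int(G_tgt.shape[0]),
    }
    return EditResult(edited=out, provenance=prov)
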