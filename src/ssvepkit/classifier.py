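"""Filter-bank CCA key classification.

For a single-trial multi-channel epoch ``x``, each candidate key ``i`` and
each harmonic sub-band ``j``, three canonical correlation analyses are run
between ``x``, the key's template SSVEP ``Y`` and its template sinusoid
``Z`` (all band-passed to sub-band ``j`` and trimmed identically).  From
the resulting weight vectors, five weighted Pearson correlations are
computed:

    r1 = corr(bx(xZ)·x, bz(xZ)·Z)      r4 = corr(bx(xY)·Y, by(xY)·Y)
    r2 = corr(bx(xY)·x, by(xY)·Y)      r5 = corr(by(YZ)·x, by(YZ)·Y)
    r3 = corr(bx(xZ)·x, bx(xZ)·Y)

where ``bc(cd)`` is the weight vector for ``c`` from CCA of ``c`` and
``d``.  Two operands are spatial-filter transfers: r3 applies the spatial
filter learned from CCA(x, Z) to the template ``Y``, and r5 applies the
template-side filter from CCA(Y, Z) to both ``x`` and ``Y`` — the standard
extended-CCA treatment of terms whose printed form would apply a scalar
sinusoid weight to a multi-channel series.

The five correlations combine per sub-band preserving sign,

    rho_ij = sum_k sign(r_k) * r_k**2            (|rho| <= 5)

and across sub-bands with harmonic-index weights into the decision
feature

    R_i = sum_j (1/j) * rho_ij**2 ,

with the key decided by argmax over ``R_i``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .epochs import EpochSet
from .templates import TemplateBank, _trim_samples, bandpass

__all__ = ["ClassificationResult", "cca_first", "fbcca_harmonic_rho", "combine_signed", "classify", "classify_epochs"]

logger = logging.getLogger(__name__)

_RANK_RTOL = 1e-10


def _as_rows(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    return a[None, :] if a.ndim == 1 else a


@dataclass
class _Basis:
    """Economy SVD of a centered series stack: ``Xc.T = q @ diag(s) @ w.T``."""

    q: np.ndarray  # (n_samples, rank) orthonormal time courses
    w: np.ndarray  # (n_series, rank)
    s: np.ndarray  # (rank,)


def _basis(x: np.ndarray) -> _Basis:
    xc = _as_rows(x)
    xc = xc - xc.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(xc.T, full_matrices=False)
    if s.size == 0 or s[0] == 0:
        raise ValueError("zero-variance side: canonical correlation undefined")
    rank = int(np.sum(s > _RANK_RTOL * s[0]))
    return _Basis(q=u[:, :rank], w=vt.T[:, :rank], s=s[:rank])


def _weights_from(basis: _Basis, direction: np.ndarray) -> np.ndarray:
    """Series weights whose projection equals ``basis.q @ direction``."""
    return basis.w @ (direction / basis.s)


def cca_first(X: np.ndarray, Y: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """First canonical correlation between two sets of series.

    Parameters
    ----------
    X, Y : ndarray
        Row-wise series, shapes ``(p, n)`` and ``(q, n)`` (1-D inputs are
        treated as a single series).  ``n`` must exceed the larger series
        count.

    Returns
    -------
    (r, weights_X, weights_Y)
        The maximized correlation (in [0, 1]) and the weight vectors of
        the first canonical pair.  Computed via rank-revealing SVD
        whitening, so rank-deficient sides (e.g. average-referenced or
        noise-free data) are handled by restricting to the spanned
        subspace.
    """
    Xr, Yr = _as_rows(X), _as_rows(Y)
    if Xr.shape[1] != Yr.shape[1]:
        raise ValueError(f"sample counts differ: {Xr.shape[1]} vs {Yr.shape[1]}")
    if Xr.shape[1] <= max(Xr.shape[0], Yr.shape[0]):
        raise ValueError("need more samples than series for CCA")
    bx, by = _basis(Xr), _basis(Yr)
    m = bx.q.T @ by.q
    u, s, vt = np.linalg.svd(m)
    r = float(np.clip(s[0], 0.0, 1.0))
    wx = _weights_from(bx, u[:, 0])
    wy = _weights_from(by, vt[0, :])
    return r, wx, wy


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    ac = a - a.mean()
    bc = b - b.mean()
    denom = np.linalg.norm(ac) * np.linalg.norm(bc)
    if denom == 0:
        raise ValueError("zero-variance projection: correlation undefined")
    return float(np.dot(ac, bc) / denom)


def fbcca_harmonic_rho(x: np.ndarray, Y: np.ndarray, Z: np.ndarray, return_r: bool = False):
    """Signed five-correlation similarity for one key and harmonic.

    ``x`` and ``Y`` are multi-channel (channels x samples) with matching
    channel sets; ``Z`` is the univariate template sinusoid.  All three
    must be band-passed and trimmed identically.
    """
    x, Y, Z = _as_rows(x), _as_rows(Y), np.asarray(Z, dtype=float).ravel()
    if x.shape != Y.shape:
        raise ValueError(f"x and Y shapes differ: {x.shape} vs {Y.shape}")
    if Z.shape[0] != x.shape[1]:
        raise ValueError(f"Z length {Z.shape[0]} != sample count {x.shape[1]}")

    _, wx_xz, wz_xz = cca_first(x, Z)
    _, wx_xy, wy_xy = cca_first(x, Y)
    _, _wz_yz, wy_yz = cca_first(Z, Y)  # template-side weights of CCA(Y, Z)

    r = np.array(
        [
            _pearson(wx_xz @ x, wz_xz * Z),
            _pearson(wx_xy @ x, wy_xy @ Y),
            _pearson(wx_xz @ x, wx_xz @ Y),
            _pearson(wx_xy @ Y, wy_xy @ Y),
            _pearson(wy_yz @ x, wy_yz @ Y),
        ]
    )
    rho = combine_signed(r)
    return (rho, r) if return_r else rho


def combine_signed(r: np.ndarray) -> float:
    """Sign-preserving combination ``sum(sign(r_k) * r_k**2)``."""
    r = np.asarray(r, dtype=float)
    return float(np.sum(np.sign(r) * r**2))


@dataclass
class ClassificationResult:
    """Per-key decision features for one epoch.

    ``features_R[i]`` is the harmonic-weighted similarity of the epoch to
    key ``i+1``'s templates; ``harmonic_rhos[i, h]`` the signed
    per-sub-band similarity.  ``decided_index`` is 1-based.
    """

    features_R: np.ndarray
    harmonic_rhos: np.ndarray
    decided_key: str
    decided_index: int
    n_harmonics_used: int


def classify(x: np.ndarray, bank: TemplateBank, n_harmonics: int | None = None) -> ClassificationResult:
    """Classify one preprocessed, channel-selected epoch against the bank.

    ``x`` has shape (n_channels, n_samples) on the **full** epoch
    timeline, with channels ordered as ``bank.selected_channels``; it is
    band-passed per harmonic and trimmed here, mirroring template
    construction.  ``n_harmonics`` limits the sub-bands used (default:
    all in the bank).

    The decided key is the argmax of ``features_R``; exact ties resolve
    to the lowest key index with a logged warning.
    """
    x = _as_rows(x)
    if not np.any(x):
        raise ValueError("all-zero epoch: correlations undefined")
    harmonics = bank.harmonics if n_harmonics is None else bank.harmonics[:n_harmonics]
    if not harmonics:
        raise ValueError("no harmonics available for classification")
    n_trim = _trim_samples(bank.trim, bank.fs)
    if x.shape[1] != bank.n_samples_full:
        raise ValueError(
            f"epoch has {x.shape[1]} samples, bank expects {bank.n_samples_full} (pre-trim)"
        )

    rhos = np.empty((bank.n_keys, len(harmonics)))
    for h, j in enumerate(harmonics):
        xf = bandpass(x, bank.bank_spec.band(j), bank.fs, bank.bank_spec.filter_order)[:, n_trim:]
        for k in range(bank.n_keys):
            rhos[k, h] = fbcca_harmonic_rho(xf, bank.ssvep[k, h], bank.sinusoid[k, h])

    weights = 1.0 / np.asarray(harmonics, dtype=float)
    features = (rhos**2 * weights[None, :]).sum(axis=1)
    best = int(np.argmax(features))
    if np.sum(features == features[best]) > 1:
        logger.warning("tie in classification features; choosing lowest key index")
    return ClassificationResult(
        features_R=features,
        harmonic_rhos=rhos,
        decided_key=bank.spec.key_order[best],
        decided_index=best + 1,
        n_harmonics_used=len(harmonics),
    )


def classify_epochs(
    epochs: EpochSet, bank: TemplateBank, n_harmonics: int | None = None
) -> list[ClassificationResult]:
    """Classify every epoch in an :class:`EpochSet` (channel-matched first)."""
    if epochs.channel_names != bank.selected_channels:
        epochs = epochs.select_channels(bank.selected_channels)
    return [classify(epochs.data[e], bank, n_harmonics) for e in range(epochs.n_epochs)]
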