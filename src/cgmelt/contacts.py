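"""Peptide-membrane contact metrics and melting-curve analysis.

A residue is "in contact" with the membrane in a frame when the minimum
periodic (minimum-image) distance between its backbone bead and any lipid
phosphate bead is at or below a threshold (default 1 nm; the boundary is
inclusive).  Averaging contacts over frames gives per-residue contact
indices; averaging those over a sequence window gives the global contact
index (GCI).  The GCI as a function of simulation temperature is a melting
curve, whose logistic midpoint defines the melting temperature Tm of the
peptide-membrane interaction.  The temperature-averaged GCI (TAGCI)
condenses one construct's melting curve into a single affinity score using
a fixed 15-residue window and the 15-rung temperature ladder.

Only orthorhombic boxes are supported; triclinic inputs are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "LabeledFrame",
    "ContactMatrix",
    "MeltingCurve",
    "MeltingFit",
    "TAGCIResult",
    "NoTransitionError",
    "DEFAULT_THRESHOLD_NM",
    "TAGCI_WINDOW_LEN",
    "residue_min_distances",
    "contact_matrix",
    "residue_contact_index",
    "global_contact_index",
    "convergence_segments",
    "melting_curve",
    "fit_melting_temperature",
    "estimate_tm_crossing",
    "tagci",
]

DEFAULT_THRESHOLD_NM = 1.0
TAGCI_WINDOW_LEN = 15


class NoTransitionError(ValueError):
    """The melting curve shows no usable binding transition."""


@dataclass
class LabeledFrame:
    """One trajectory frame reduced to the beads the contact metric needs."""

    protein_backbone: np.ndarray  # (n_residues, 3) nm
    phosphate_beads: np.ndarray  # (n_phosphates, 3) nm
    box: np.ndarray  # 3 orthorhombic edge lengths, nm

    def __post_init__(self) -> None:
        self.protein_backbone = np.atleast_2d(np.asarray(self.protein_backbone, float))
        self.phosphate_beads = np.atleast_2d(np.asarray(self.phosphate_beads, float))
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        if np.any(self.box <= 0):
            raise ValueError("box edges must be positive")
        if self.phosphate_beads.shape[0] < 1:
            raise ValueError("frame needs at least one phosphate bead")


@dataclass
class ContactMatrix:
    """Binary residues x frames membrane-contact record at one temperature."""

    contacts: np.ndarray  # (n_residues, n_frames) of {0, 1}
    threshold: float
    temperature: float | None = None

    def __post_init__(self) -> None:
        self.contacts = np.asarray(self.contacts)
        if self.contacts.ndim != 2:
            raise ValueError("contacts must be residues x frames")
        if not np.isin(self.contacts, (0, 1)).all():
            raise ValueError("contact entries must be binary")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")

    @property
    def n_residues(self) -> int:
        return self.contacts.shape[0]

    @property
    def n_frames(self) -> int:
        return self.contacts.shape[1]


@dataclass
class MeltingCurve:
    temperatures: np.ndarray  # K, strictly increasing
    global_contact_index: np.ndarray  # per-temperature GCI in [0, 1]
    segment_std: np.ndarray  # per-temperature spread across trajectory segments

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, float)
        self.global_contact_index = np.asarray(self.global_contact_index, float)
        self.segment_std = np.asarray(self.segment_std, float)
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        g = self.global_contact_index
        if np.any((g < 0) | (g > 1)):
            raise ValueError("global contact index must lie in [0, 1]")


@dataclass
class MeltingFit:
    """Four-parameter logistic fit b + (a - b) / (1 + exp((T - tm)/s))."""

    tm: float  # K
    tm_halfwidth: float  # 1-sigma half-width from the fit covariance, K
    steepness: float  # K
    high_plateau: float  # a, low-T occupancy
    low_plateau: float  # b, high-T occupancy
    residual_rms: float


@dataclass
class TAGCIResult:
    construct_name: str
    window_start: int  # 1-based residue index
    window_len: int
    value: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 1.0):
            raise ValueError("TAGCI must lie in [0, 1]")


def _min_image_distances(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """(len(a), len(b)) minimum-image distances in an orthorhombic box."""
    d = a[:, None, :] - b[None, :, :]
    d -= box * np.round(d / box)
    return np.sqrt((d * d).sum(axis=-1))


def residue_min_distances(frame: LabeledFrame) -> np.ndarray:
    """Per-residue minimum distance (nm) to any phosphate bead, minimum image."""
    return _min_image_distances(
        frame.protein_backbone, frame.phosphate_beads, frame.box
    ).min(axis=1)


def _shared_layout(frames: Sequence[LabeledFrame]) -> bool:
    # synthetic campaigns reuse one phosphate array and box across frames;
    # identity lets us vectorize over frames without changing the result
    p0, b0 = frames[0].phosphate_beads, frames[0].box
    return all(f.phosphate_beads is p0 and f.box is b0 for f in frames)


def contact_matrix(
    frames: Sequence[LabeledFrame],
    threshold: float = DEFAULT_THRESHOLD_NM,
    temperature: float | None = None,
) -> ContactMatrix:
    """Binary contact record: entry (r, f) = 1 iff residue r is within
    ``threshold`` nm (inclusive) of any phosphate in frame f."""
    if len(frames) < 1:
        raise ValueError("need at least one frame")
    if _shared_layout(frames) and len(frames) > 1:
        phos = frames[0].phosphate_beads
        box = frames[0].box
        bb = np.stack([f.protein_backbone for f in frames])  # (F, R, 3)
        n_frames = bb.shape[0]
        cols = []
        inv_box = 1.0 / box
        thr2 = threshold * threshold
        chunk = max(1, int(4e6 // max(1, bb.shape[1] * phos.shape[0])))
        for s in range(0, n_frames, chunk):
            d = bb[s : s + chunk, :, None, :] - phos[None, None, :, :]
            d -= box * np.rint(d * inv_box)
            dist2 = np.einsum("frpc,frpc->frp", d, d).min(axis=2)  # (chunk, R)
            cols.append(dist2 <= thr2)
        mat = np.concatenate(cols, axis=0).T.astype(np.uint8)
    else:
        mat = np.stack(
            [residue_min_distances(f) <= threshold for f in frames], axis=1
        ).astype(np.uint8)
    return ContactMatrix(mat, threshold=threshold, temperature=temperature)


def residue_contact_index(matrix: ContactMatrix) -> np.ndarray:
    """Per-residue fraction of frames in contact."""
    return matrix.contacts.mean(axis=1)


def _resolve_window(n_residues: int, window: tuple[int, int] | None) -> slice:
    if window is None:
        return slice(0, n_residues)
    start, length = window
    if start < 1 or length < 1 or start - 1 + length > n_residues:
        raise ValueError(
            f"window (start={start}, len={length}) exceeds the "
            f"{n_residues}-residue sequence"
        )
    return slice(start - 1, start - 1 + length)


def global_contact_index(
    per_residue: np.ndarray, window: tuple[int, int] | None = None
) -> float:
    """Unweighted mean of per-residue indices over a (1-based start, length)
    window, or over the full sequence."""
    per_residue = np.asarray(per_residue, float)
    return float(per_residue[_resolve_window(per_residue.size, window)].mean())


def convergence_segments(
    matrix: ContactMatrix,
    n_segments: int = 3,
    window: tuple[int, int] | None = None,
) -> tuple[np.ndarray, float]:
    """Global contact index per consecutive trajectory segment, plus their
    population standard deviation.

    Frames are split into ``n_segments`` consecutive blocks; when the frame
    count is not divisible, earlier blocks take the remainder (10 frames in
    3 segments -> sizes 4/3/3).
    """
    n = matrix.n_frames
    if n < n_segments:
        raise ValueError(f"need at least {n_segments} frames, got {n}")
    base, rem = divmod(n, n_segments)
    sizes = [base + (1 if i < rem else 0) for i in range(n_segments)]
    edges = np.cumsum([0] + sizes)
    sel = _resolve_window(matrix.n_residues, window)
    vals = np.array(
        [matrix.contacts[sel, edges[i] : edges[i + 1]].mean() for i in range(n_segments)]
    )
    return vals, float(np.std(vals))


def melting_curve(
    matrices: Mapping[float, ContactMatrix] | Sequence[ContactMatrix],
    window: tuple[int, int] | None = None,
    n_segments: int = 3,
) -> MeltingCurve:
    """Global contact index vs temperature, with per-temperature segment std.

    ``matrices`` is either a mapping {temperature: ContactMatrix} or a
    sequence of matrices carrying their own temperatures.  Output is sorted
    by temperature regardless of input order.
    """
    if isinstance(matrices, Mapping):
        pairs = [(float(t), m) for t, m in matrices.items()]
    else:
        pairs = []
        for m in matrices:
            if m.temperature is None:
                raise ValueError("matrix without temperature label")
            pairs.append((float(m.temperature), m))
    if len(pairs) < 2:
        raise ValueError("need at least two temperatures for a melting curve")
    pairs.sort(key=lambda tm: tm[0])
    temps, gci, std = [], [], []
    for t, m in pairs:
        sel = _resolve_window(m.n_residues, window)
        temps.append(t)
        gci.append(float(m.contacts[sel].mean()))
        std.append(convergence_segments(m, n_segments, window)[1])
    return MeltingCurve(np.array(temps), np.array(gci), np.array(std))


def _logistic(t, a, b, tm, s):
    return b + (a - b) / (1.0 + np.exp((t - tm) / s))


def fit_melting_temperature(curve: MeltingCurve, min_drop: float = 0.2) -> MeltingFit:
    """Melting temperature from a least-squares logistic fit.

    Requires the curve to actually melt: the GCI must drop by at least
    ``min_drop`` from its maximum to its minimum and trend downward,
    otherwise :class:`NoTransitionError` is raised.  Tm is the logistic
    midpoint; its half-width is the 1-sigma standard error from the fit
    covariance.
    """
    from scipy.optimize import curve_fit

    t = curve.temperatures
    g = curve.global_contact_index
    drop = g.max() - g.min()
    if drop < min_drop:
        raise NoTransitionError(
            f"global contact index spans only {drop:.3f} (< {min_drop}); "
            "no melting transition to fit"
        )
    if g[t <= t.min() + 1e-9][0] < g[t >= t.max() - 1e-9][-1]:
        raise NoTransitionError("curve increases with temperature; not a melting curve")

    half = 0.5 * (g.max() + g.min())
    tm0 = float(t[np.argmin(np.abs(g - half))])
    span = float(t.max() - t.min())
    p0 = (float(g.max()), float(g.min()), tm0, max(span / 14.0, 1.0))
    bounds = ([0.0, 0.0, t.min() - span, 1e-3], [1.5, 1.5, t.max() + span, 10.0 * span])
    popt, pcov = curve_fit(
        _logistic, t, g, p0=p0, bounds=bounds, maxfev=20000,
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    a, b, tm, s = (float(v) for v in popt)
    resid = g - _logistic(t, *popt)
    tm_err = float(np.sqrt(pcov[2, 2])) if np.all(np.isfinite(pcov)) else float("nan")
    return MeltingFit(
        tm=tm,
        tm_halfwidth=tm_err,
        steepness=s,
        high_plateau=a,
        low_plateau=b,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def estimate_tm_crossing(curve: MeltingCurve) -> float:
    """Fallback Tm estimator: linear-interpolated crossing of the half-range.

    Robust for noisy curves where the logistic fit is poorly conditioned.
    """
    t = curve.temperatures
    g = curve.global_contact_index
    half = 0.5 * (g.max() + g.min())
    below = np.nonzero(g <= half)[0]
    if below.size == 0 or below[0] == 0:
        raise NoTransitionError("curve never crosses its half-range from above")
    j = below[0]
    t0, t1, g0, g1 = t[j - 1], t[j], g[j - 1], g[j]
    if g0 == g1:
        return float(0.5 * (t0 + t1))
    return float(t0 + (g0 - half) * (t1 - t0) / (g0 - g1))


def tagci(
    matrices: Mapping[float, ContactMatrix] | Sequence[ContactMatrix],
    construct_name: str,
    window_len: int = TAGCI_WINDOW_LEN,
    window_start: int = 1,
) -> TAGCIResult:
    """Temperature-averaged global contact index of one construct.

    The GCI of a fixed window (by default the first 15 residues) is
    averaged with equal weights over the temperature ladder.
    """
    mats = list(matrices.values()) if isinstance(matrices, Mapping) else list(matrices)
    if len(mats) < 2:
        raise ValueError("TAGCI needs the multi-temperature ladder")
    n_res = mats[0].n_residues
    if n_res < window_start - 1 + window_len:
        raise ValueError(
            f"construct {construct_name!r} has {n_res} residues; TAGCI with "
            f"window_start={window_start} requires at least "
            f"{window_start - 1 + window_len}"
        )
    window = (window_start, window_len)
    vals = [global_contact_index(residue_contact_index(m), window) for m in mats]
    return TAGCIResult(
        construct_name=construct_name,
        window_start=window_start,
        window_len=window_len,
        value=float(np.mean(vals)),
    )
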