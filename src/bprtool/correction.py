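"""BPR-corrected traces: model-based subtraction and the interpolation comparator.

Model-based correction evaluates each blink's fitted kernel, scaled by that
blink's estimated amplitude, at the native sampling times over the 3-s
window after the blink offset, and subtracts it — a counterfactual estimate
of what the trace would have been had the blink not occurred.  The
comparator replaces each blink's window with a straight line, the common
practice this package argues against: it removes the blink response but
also any genuine event-locked signal inside the window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .inference import FittedModel
from .model import gamma_kernel
from .preprocess import BlinkTable, PreprocessParams
from .signal_io import PupilTrace

__all__ = ["CorrectionResult", "subtract_bpr", "interpolate_blinks"]

#: Kernel/model window length in seconds; correction support is truncated here.
MODEL_WINDOW = 3.0


@dataclass
class CorrectionResult:
    """A corrected trace plus the per-blink removed components."""

    corrected: PupilTrace
    removed: list = field(default_factory=list)  # (blink_index, theta, component)
    method: str = "model_based"


def subtract_bpr(
    trace: PupilTrace,
    blinks: BlinkTable,
    model: FittedModel,
) -> CorrectionResult:
    """Subtract each blink's estimated response from the trace.

    For blink ``j`` the component ``theta_j * h`` is evaluated at the
    native sampling times over ``[offset_j, offset_j + 3 s]`` (the kernel
    is truncated at the model window) and subtracted; overlapping
    footprints subtract additively.  Samples outside every footprint are
    untouched bit-exactly.
    """
    out = trace.copy()
    if model.shape is None or len(model.amplitudes) == 0:
        if len(blinks) > 0:
            warnings.warn(
                "model has no fitted kernel; returning the trace unchanged",
                stacklevel=2,
            )
        return CorrectionResult(corrected=out, removed=[], method="model_based")

    # Peri-blink artifact spans hold interpolated (chord) data, so the
    # blink component they contain is the chord of the kernel, not the
    # kernel itself; subtracting the raw kernel there would over-correct.
    art_windows = []
    if blinks.post_end is not None and len(blinks.post_end):
        art_windows = list(zip(blinks.offset, blinks.post_end))

    removed = []
    t = out.time
    for k, theta in enumerate(model.amplitudes.theta):
        j = int(model.blink_index[k]) if model.blink_index.size else k
        offset = blinks.offset[j]
        i0 = np.searchsorted(t, offset, side="left")
        i1 = np.searchsorted(t, offset + MODEL_WINDOW, side="right")
        rel = t[i0:i1] - offset
        component = theta * gamma_kernel(model.shape, rel)
        for a, b in art_windows:
            if b <= t[i0] or a >= t[min(i1, len(t) - 1)]:
                continue
            w0 = np.searchsorted(t, a, side="left") - i0
            w1 = np.searchsorted(t, b, side="right") - i0
            w0 = max(w0, 0)
            w1 = min(w1, len(component))
            if w1 - w0 < 2:
                continue
            component[w0:w1] = np.linspace(component[w0], component[w1 - 1],
                                           w1 - w0)
        out.pupil[i0:i1] -= component
        removed.append((j, float(theta), component))
    return CorrectionResult(corrected=out, removed=removed, method="model_based")


def interpolate_blinks(
    trace: PupilTrace,
    blinks: BlinkTable,
    span: float = 3.0,
    params: PreprocessParams | None = None,
) -> CorrectionResult:
    """Replace each blink's window with a straight line (comparator method).

    The window runs from the pre-artifact start (onset minus the artifact
    margin, or the blink table's ``pre_start`` when present) to
    ``offset + span``; overlapping windows are merged before interpolation.
    The line joins the trace values at the samples just outside the window
    boundaries — the artifact-window edges, not the contaminated blink
    samples themselves.
    """
    params = params or PreprocessParams()
    out = trace.copy()
    if len(blinks) == 0:
        return CorrectionResult(corrected=out, removed=[], method="interpolation")

    pre = (
        blinks.pre_start
        if blinks.pre_start is not None and len(blinks.pre_start)
        else blinks.onset - params.pre_artifact
    )
    ends = blinks.offset + span
    # merge overlapping windows
    windows = []
    lo, hi = pre[0], ends[0]
    for j in range(1, len(blinks)):
        if pre[j] <= hi:
            hi = max(hi, ends[j])
        else:
            windows.append((lo, hi))
            lo, hi = pre[j], ends[j]
    windows.append((lo, hi))

    t = out.time
    n = len(out)
    removed = []
    for lo, hi in windows:
        i0 = np.searchsorted(t, lo, side="left")
        i1 = np.searchsorted(t, hi, side="right")
        if i0 >= n or i1 <= 0 or i1 <= i0:
            continue
        left = i0 - 1
        right = i1
        if left < 0 and right >= n:
            continue
        if left < 0:
            warnings.warn("interpolation window reaches trace start; holding value",
                          stacklevel=2)
            line = np.full(i1 - i0, out.pupil[right])
        elif right >= n:
            warnings.warn("interpolation window reaches trace end; holding value",
                          stacklevel=2)
            line = np.full(i1 - i0, out.pupil[left])
        else:
            line = np.interp(t[i0:i1], [t[left], t[right]], [out.pupil[left], out.pupil[right]])
        removed.append((int(i0), out.pupil[i0:i1] - line))
        out.pupil[i0:i1] = line
    return CorrectionResult(corrected=out, removed=removed, method="interpolation")
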