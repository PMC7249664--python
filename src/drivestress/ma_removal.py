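"""Two-channel SPR motion-artifact removal by local-energy-weighted fusion.

Hand movement on the steering wheel injects bursts of energy into the SPR
channel of the engaged hand, and usually into only one hand at a time.  The
fused output is a soft weighted combination of the two hand channels that
follows the locally "smoother" channel: each sample's weight on a channel
decreases as that channel's local energy rises.

Local energy is the moving average of the squared *first difference* of the
signal, so the slow tonic SPR level does not dominate the weighting — only
fast activity (artifacts, and to a lesser degree phasic transients shared by
both hands) does.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Channel

__all__ = ["FusionParams", "local_energy", "fuse_spr", "evaluate_against_reference"]


@dataclass(frozen=True)
class FusionParams:
    """Fusion tuning: energy window (shorter than a phasic transient, longer
    than an artifact spike), weight sharpening exponent, and a regularizer
    for the all-quiet case."""

    energy_window_s: float = 2.0
    sharpening_exponent: float = 2.0
    epsilon: float = 1e-12

    def __post_init__(self) -> None:
        if self.energy_window_s <= 0:
            raise ValueError("energy_window_s must be > 0")
        if self.sharpening_exponent < 0:
            raise ValueError("sharpening_exponent must be >= 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


def _truncated_moving_average(x: np.ndarray, win: int) -> np.ndarray:
    """Symmetric moving average; edge windows are truncated, not padded."""
    ones = np.ones(win)
    num = np.convolve(x, ones, mode="same")
    den = np.convolve(np.ones_like(x), ones, mode="same")
    return num / den


def local_energy(x: Channel, window_s: float) -> Channel:
    """Moving average of the squared first difference of ``x``.

    Same length as the input; the first sample's difference is defined as 0.
    Non-negative everywhere; zero for a constant signal.
    """
    if window_s <= 0:
        raise ValueError("window_s must be > 0")
    win = int(round(window_s * x.fs_hz))
    if win < 1 or win >= x.samples.size:
        raise ValueError("energy window must be shorter than the signal")
    d = np.diff(x.samples, prepend=x.samples[0])
    return x.copy_with(_truncated_moving_average(d * d, win), name=f"{x.name}_energy")


def fuse_spr(spr_left: Channel, spr_right: Channel, params: FusionParams | None = None) -> Channel:
    """Fuse the two hand SPR channels into one cleaned signal.

    With local energies ``E_L``, ``E_R`` and exponent ``p``::

        w_L = (E_R^p + eps/2) / (E_L^p + E_R^p + eps),   w_R = 1 - w_L
        out = w_L * left + w_R * right

    Weights lie in [0, 1] and sum to 1 at every sample, so the output is a
    sample-wise convex combination of the inputs: where the left hand is
    noisy (``E_L >> E_R``) the output tracks the right channel and vice
    versa; equal energies give the plain average.
    """
    params = params if params is not None else FusionParams()
    if spr_left.fs_hz != spr_right.fs_hz or spr_left.samples.size != spr_right.samples.size:
        raise ValueError("hand channels must share sampling rate and length")
    e_l = local_energy(spr_left, params.energy_window_s).samples
    e_r = local_energy(spr_right, params.energy_window_s).samples
    p = params.sharpening_exponent
    el_p, er_p = e_l**p, e_r**p
    w_l = (er_p + params.epsilon / 2.0) / (el_p + er_p + params.epsilon)
    out = w_l * spr_left.samples + (1.0 - w_l) * spr_right.samples
    return Channel("spr_fused", spr_left.unit, spr_left.fs_hz, out)


def evaluate_against_reference(
    out: Channel, ref: Channel, spr_left: Channel, spr_right: Channel
) -> dict[str, float]:
    """RMS of each trace and variance of each difference-to-reference.

    This is the statistic set used to validate the fusion against an
    artifact-free reference: a successful fusion has ``var_diff_out`` below
    both single-hand values and an RMS close to the reference's.
    """
    traces = {"out": out, "ref": ref, "left": spr_left, "right": spr_right}
    n = {c.samples.size for c in traces.values()}
    if len(n) != 1:
        raise ValueError("all traces must have equal length")
    result: dict[str, float] = {}
    for key, ch in traces.items():
        result[f"rms_{key}"] = float(np.sqrt(np.mean(ch.samples**2)))
    for key in ("out", "left", "right"):
        result[f"var_diff_{key}"] = float(np.var(traces[key].samples - ref.samples))
    return result
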