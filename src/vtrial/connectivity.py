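"""Phase Lag Index (PLI) functional connectivity.

PLI quantifies the asymmetry of the distribution of instantaneous phase
differences between two signals:

    PLI = | < sign( sin(dphi(t)) ) > |

It is 0 when the phase difference is symmetric around 0 mod pi (no
coupling, or zero-lag coupling of the kind volume conduction produces)
and 1 for a consistent nonzero lag.  Phases are taken from the analytic
signal of the band-passed trace (default 4-13 Hz, covering the model's
theta-alpha activity), with filter-edge samples trimmed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

__all__ = ["PLIMatrix", "instantaneous_phase", "pli", "pli_matrix"]

PHASE_BAND = (4.0, 13.0)
EDGE_FRACTION = 0.1


@dataclass
class PLIMatrix:
    values: np.ndarray   # symmetric, zero diagonal, in [0, 1]
    global_mean: float   # mean over distinct pairs


def instantaneous_phase(signal: np.ndarray, fs: float,
                        band: tuple[float, float] = PHASE_BAND,
                        edge_fraction: float = EDGE_FRACTION) -> np.ndarray:
    """Analytic-signal phase (radians) of the band-limited trace.

    ``signal`` is 1-D or time x channels; ``edge_fraction`` of the
    samples is trimmed from each end to discard filter/Hilbert edge
    effects.  A constant channel has no defined phase and is rejected.
    """
    x = np.asarray(signal, dtype=float)
    if x.shape[0] < 4:
        raise ValueError("signal too short for phase estimation")
    if np.ptp(x, axis=0).min() == 0:
        raise ValueError("constant signal: instantaneous phase undefined")
    sos = butter(4, band, btype="bandpass", fs=fs, output="sos")
    xf = sosfiltfilt(sos, x, axis=0)
    phase = np.angle(hilbert(xf, axis=0))
    n_edge = int(round(edge_fraction * x.shape[0]))
    return phase[n_edge: x.shape[0] - n_edge] if n_edge else phase


def pli(phase_x: np.ndarray, phase_y: np.ndarray) -> float:
    """PLI of two phase series: ``|mean(sign(sin(phi_x - phi_y)))|``.

    Symmetric in its arguments, bounded in [0, 1]; samples with
    ``sin(dphi)`` exactly 0 contribute 0 to the mean but count in the
    denominator.
    """
    phase_x = np.asarray(phase_x, dtype=float)
    phase_y = np.asarray(phase_y, dtype=float)
    if phase_x.shape != phase_y.shape:
        raise ValueError("phase series must have equal length")
    return float(np.abs(np.mean(np.sign(np.sin(phase_x - phase_y)))))


def pli_matrix(signals: np.ndarray, fs: float,
               band: tuple[float, float] = PHASE_BAND,
               edge_fraction: float = EDGE_FRACTION) -> PLIMatrix:
    """All-pairs PLI of a multichannel recording plus its global mean."""
    signals = np.asarray(signals, dtype=float)
    if signals.ndim != 2 or signals.shape[1] < 2:
        raise ValueError("pli_matrix needs a 2-D time x channels array "
                         "with at least 2 channels")
    phase = instantaneous_phase(signals, fs, band, edge_fraction)
    n = signals.shape[1]
    values = np.zeros((n, n))
    for i in range(n):
        s = np.sign(np.sin(phase[:, i, None] - phase[:, i + 1:]))
        vals = np.abs(s.mean(axis=0))
        values[i, i + 1:] = vals
        values[i + 1:, i] = vals
    iu = np.triu_indices(n, 1)
    return PLIMatrix(values=values, global_mean=float(values[iu].mean()))
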