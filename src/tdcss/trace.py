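"""Per-cell secretion-signal traces.

A trace is the background-referenced mean fluorescence of one microwell
(one cell, one cytokine channel) sampled at a fixed scan interval after
stimulation.  Time is in hours since stimulus addition; the first scan is
at t = scan_interval_h.  The signal is referenced to the first acquired
frame, so by construction it starts near zero and rises with drift slope
``a`` until the secretion onset, after which it rises with slope ``b > a``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SchemaError


@dataclass
class SecretionTrace:
    """One cell's secretion signal versus time for one cytokine channel.

    Parameters
    ----------
    cell_id : str
        Identifier of the well/cell.
    times : ndarray of float
        Hours since stimulation, strictly increasing, uniformly spaced.
    signal : ndarray of float
        Secretion signal in arbitrary fluorescence units, referenced to
        the first frame.
    channel : str
        Cytokine channel label (e.g. ``"IL-13"``).
    scan_interval_h : float or None
        Scan interval in hours.  Inferred from ``times`` when omitted.
    """

    cell_id: str
    times: np.ndarray
    signal: np.ndarray
    channel: str = "ch1"
    scan_interval_h: float | None = field(default=None)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.ndim != 1 or self.signal.ndim != 1:
            raise SchemaError(f"trace {self.cell_id}: times and signal must be 1-D")
        if self.times.size != self.signal.size:
            raise SchemaError(
                f"trace {self.cell_id}: times ({self.times.size}) and signal "
                f"({self.signal.size}) lengths differ"
            )
        if self.times.size < 2:
            raise SchemaError(f"trace {self.cell_id}: need at least 2 samples")
        if not np.all(np.isfinite(self.times)):
            raise SchemaError(f"trace {self.cell_id}: non-finite time values")
        if np.any(np.diff(self.times) <= 0):
            raise SchemaError(f"trace {self.cell_id}: times must be strictly increasing")
        if self.scan_interval_h is None:
            self.scan_interval_h = float(np.median(np.diff(self.times)))

    def __len__(self) -> int:
        return int(self.times.size)

    def truncated(self, t_max: float) -> "SecretionTrace":
        """Return the causal prefix of the trace with times <= ``t_max``."""
        keep = self.times <= t_max + 1e-12
        return SecretionTrace(
            cell_id=self.cell_id,
            times=self.times[keep],
            signal=self.signal[keep],
            channel=self.channel,
            scan_interval_h=self.scan_interval_h,
        )
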