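"""Superfusion release arithmetic for radiolabelled transmitter experiments.

A slice preloaded with tritiated transmitter is perfused and the effluent
collected in fixed-duration samples (3 min by default).  The only
measurable anchor after the experiment is the residual tissue content, so
the tissue content at the start of each sample is reconstructed backwards:

    tissue(k) = tissue_after + sum(released[k:])

Fractional release of sample k is released(k) / tissue(k) * 100.  Basal
outflow is the mean fractional release of consecutive drug-free samples
before the stimulus, and the evoked (net) release is the mean fractional
release over the stimulation response window minus the basal outflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ReleaseSeries",
    "fractional_release",
    "uptake",
    "basal_outflow",
    "evoked_release",
]


@dataclass
class ReleaseSeries:
    released_bq: np.ndarray  # per-sample released radioactivity
    tissue_after_bq: float  # residual tissue content after the last sample
    tissue_mass_g: float | None = None
    stim_sample_index: int | None = None
    sample_duration_s: float = 180.0

    def __post_init__(self) -> None:
        self.released_bq = np.asarray(self.released_bq, float)
        if np.any(self.released_bq < 0) or self.tissue_after_bq < 0:
            raise ValueError("released amounts and tissue content must be >= 0")

    @property
    def n_samples(self) -> int:
        return len(self.released_bq)

    def tissue_at_start_bq(self) -> np.ndarray:
        """Tissue content at the start of each sample, reconstructed from
        the residual content; index 0 equals the initial load exactly."""
        return self.tissue_after_bq + np.cumsum(self.released_bq[::-1])[::-1]


def fractional_release(series: ReleaseSeries) -> np.ndarray:
    """Per-sample release as a percentage of the tissue content at the
    start of that sample."""
    tissue = series.tissue_at_start_bq()
    if np.any(tissue <= 0):
        raise ValueError("zero tissue content encountered; fractional release undefined")
    return 100.0 * series.released_bq / tissue


def uptake(series: ReleaseSeries) -> float:
    """Total tritium load per unit tissue mass (Bq/g): released plus
    residual content divided by the wet mass."""
    if series.tissue_mass_g is None or series.tissue_mass_g <= 0:
        raise ValueError("tissue mass required for uptake")
    return (float(series.released_bq.sum()) + series.tissue_after_bq) / series.tissue_mass_g


def basal_outflow(series: ReleaseSeries, pre_stim_samples: int = 2) -> float:
    """Mean fractional release over the consecutive drug-free samples
    immediately preceding the stimulus."""
    if series.stim_sample_index is None:
        raise ValueError("stimulus sample index not set")
    s = series.stim_sample_index
    if s < pre_stim_samples:
        raise ValueError("stimulus too early: not enough drug-free samples")
    fr = fractional_release(series)
    return float(fr[s - pre_stim_samples : s].mean())


def evoked_release(
    series: ReleaseSeries,
    response_samples: int = 3,
    pre_stim_samples: int = 2,
) -> float:
    """Net stimulus-evoked fractional release (percentage points).

    The response window is the stimulation sample plus the following
    ``response_samples - 1`` samples (clipped to the series end); its mean
    fractional release minus the basal outflow is returned.
    """
    if series.stim_sample_index is None:
        raise ValueError("stimulus sample index not set")
    s = series.stim_sample_index
    if s >= series.n_samples:
        raise ValueError("no post-stimulus samples")
    fr = fractional_release(series)
    window = fr[s : min(s + response_samples, series.n_samples)]
    return float(window.mean()) - basal_outflow(series, pre_stim_samples)
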