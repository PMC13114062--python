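"""Time-domain descriptors: amplitude statistics and Hjorth parameters."""

from __future__ import annotations

import numpy as np

from ..errors import DataError

TIME_FEATURE_NAMES = [
    "Std",
    "PeakToPeak",
    "RMS",
    "HjorthActivity",
    "HjorthMobility",
    "HjorthComplexity",
]


def hjorth_parameters(x: np.ndarray) -> tuple[float, float, float]:
    """Hjorth activity, mobility and complexity.

    activity   = var(x)
    mobility   = sqrt(var(x') / var(x))
    complexity = mobility(x') / mobility(x)

    with x' the first difference.  For a constant signal mobility and
    complexity are undefined; the documented sentinels are mobility 0
    and complexity 1 (a pure sinusoid also has complexity 1, so the
    sentinel is the 'maximally regular' limit).
    """
    var_x = float(np.var(x))
    if var_x == 0.0:
        return 0.0, 0.0, 1.0
    dx = np.diff(x)
    var_dx = float(np.var(dx))
    mobility = np.sqrt(var_dx / var_x)
    if var_dx == 0.0:
        return var_x, mobility, 1.0
    ddx = np.diff(dx)
    mobility_dx = np.sqrt(float(np.var(ddx)) / var_dx)
    complexity = mobility_dx / mobility if mobility > 0 else 1.0
    return var_x, float(mobility), float(complexity)


def time_features(x: np.ndarray) -> dict[str, float]:
    """The six time-domain features of one 1-D epoch."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise DataError("epoch too short for time-domain features (need >= 3)")
    if not np.all(np.isfinite(x)):
        raise DataError("non-finite samples in epoch")
    activity, mobility, complexity = hjorth_parameters(x)
    return {
        "Std": float(np.std(x)),
        "PeakToPeak": float(np.max(x) - np.min(x)),
        "RMS": float(np.sqrt(np.mean(x**2))),
        "HjorthActivity": activity,
        "HjorthMobility": mobility,
        "HjorthComplexity": complexity,
    }
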