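"""Enzyme-linked lectin assay (ELLA) plate normalization.

Raw A405 absorbances, read per lectin in replicate alongside a no-lectin
background control, are converted to percent reactivity: the mean background
is subtracted from every reading, per-lectin means are computed, and all
values are scaled so the strongest-responding lectin equals 100%. Replicate
spread is reported as the sample standard deviation (n-1 denominator) on the
same percent scale. Negative background-subtracted values are kept as-is by
default (``clamp_zero=True`` floors them at 0 before averaging).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .model import ShellomeError


@dataclass(frozen=True)
class LectinPlate:
    lectins: tuple[str, ...]
    absorbance: Mapping[str, Sequence[float]]
    background: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.background:
            raise ShellomeError("background required")
        for lectin in self.lectins:
            readings = self.absorbance.get(lectin, ())
            if len(readings) < 1:
                raise ShellomeError(f"{lectin}: at least one replicate required")
            if any(r < 0 for r in readings):
                raise ShellomeError(f"{lectin}: negative absorbance reading")
        if any(r < 0 for r in self.background):
            raise ShellomeError("negative background reading")


@dataclass(frozen=True)
class NormalizedReactivity:
    """Percent-of-maximum reactivity per lectin: (mean_percent, sd_percent)."""

    values: Mapping[str, tuple[float, float]]

    def mean_percent(self, lectin: str) -> float:
        return self.values[lectin][0]

    def sd_percent(self, lectin: str) -> float:
        return self.values[lectin][1]

    def max_lectins(self, tol: float = 1e-9) -> list[str]:
        top = max(v[0] for v in self.values.values())
        return [l for l, v in self.values.items() if abs(v[0] - top) <= tol]


def _sample_sd(values: np.ndarray) -> float:
    # single replicate: spread is undefined with an n-1 denominator; report 0
    if values.size < 2:
        return 0.0
    return float(np.std(values, ddof=1))


def normalize_plate(plate: LectinPlate, clamp_zero: bool = False) -> NormalizedReactivity:
    """Background-subtract and scale to the strongest lectin = 100%."""
    bg = float(np.mean(plate.background))
    subtracted: dict[str, np.ndarray] = {}
    for lectin in plate.lectins:
        vals = np.asarray(plate.absorbance[lectin], dtype=float) - bg
        if clamp_zero:
            vals = np.clip(vals, 0.0, None)
        subtracted[lectin] = vals
    means = {l: float(np.mean(v)) for l, v in subtracted.items()}
    top = max(means.values())
    if top <= 0:
        raise ShellomeError("no signal above background")
    values = {
        l: (100.0 * means[l] / top, 100.0 * _sample_sd(subtracted[l]) / top)
        for l in plate.lectins
    }
    return NormalizedReactivity(values=values)


def plot_reactivity(reactivity: NormalizedReactivity, path: str) -> None:
    """Bar chart of percent reactivity with SD error bars (optional extra)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lectins = list(reactivity.values)
    means = [reactivity.mean_percent(l) for l in lectins]
    sds = [reactivity.sd_percent(l) for l in lectins]
    fig, ax = plt.subplots(figsize=(0.45 * len(lectins) + 2, 4))
    ax.bar(lectins, means, yerr=sds, capsize=3, color="#4878a8")
    ax.set_ylabel("reactivity (% of maximum)")
    ax.tick_params(axis="x", rotation=90)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
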