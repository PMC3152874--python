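"""Result container shared by the two genome-scan methods."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ScanResults"]


@dataclass
class ScanResults:
    """Outcome of a single-QTL scan along one chromosome.

    ``profile`` holds one row per evaluated position with the test statistic
    (column named after ``statistic``, "LOD" or "F") and per-position
    estimates.  Peak quantities and the positional support/confidence
    interval are filled by the scanning routine.
    """

    statistic: str
    chromosome: int | None
    profile: pd.DataFrame = field(repr=False)
    peak_position: float = np.nan
    peak_value: float = np.nan
    support_interval: tuple[float, float] | None = None
    effect_estimate: float = np.nan
    effect_sd_units: float = np.nan
    effect_se_sd_units: float = np.nan
    significance_class: str = "none"
    flanking_markers: tuple[str, str] | None = None
    n: int = 0
    metadata: dict = field(default_factory=dict)

    @property
    def positions(self) -> np.ndarray:
        return self.profile["position_cM"].to_numpy()

    @property
    def values(self) -> np.ndarray:
        return self.profile[self.statistic].to_numpy()

    def summary(self) -> str:
        ci = (
            f"[{self.support_interval[0]:.1f}, {self.support_interval[1]:.1f}]"
            if self.support_interval
            else "n/a"
        )
        flank = "-".join(self.flanking_markers) if self.flanking_markers else "n/a"
        lines = [
            f"Single-QTL scan ({self.statistic})",
            "=" * 40,
            f"chromosome:        {self.chromosome}",
            f"daughters (n):     {self.n}",
            f"positions scanned: {len(self.profile)}",
            f"peak position:     {self.peak_position:.1f} cM",
            f"peak {self.statistic}:          {self.peak_value:.2f}",
            f"interval:          {ci}",
            f"flanking markers:  {flank}",
            f"effect (SD units): {self.effect_sd_units:+.2f}",
            f"significance:      {self.significance_class}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None, **kwargs):
        """Plot the statistic profile along the chromosome."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 3))
        ax.plot(self.positions, self.values, **kwargs)
        ax.axvline(self.peak_position, ls=":", color="grey")
        ax.set_xlabel("position (cM)")
        ax.set_ylabel(self.statistic)
        if self.chromosome is not None:
            ax.set_title(f"chromosome {self.chromosome}")
        return ax
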