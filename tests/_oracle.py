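"""Closed-form cascade oracle for even-spacing simulations.

Independent of the time-stepping simulator: emergence times come from
inverting the closed-form elongation curves, so lateral counts and total
lengths follow without any discretisation.  Only valid when every branch
point emits (emergence probability 1 everywhere) and growth is linear with
an optional elongation-reduction schedule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass
class CascadeOracle:
    r_tap: float
    r_lateral: float
    ln: float
    apical: float = 2.5
    basal: float = 0.5
    onset: float | None = None
    peak: float | None = None
    stub_length: float = 0.5
    nob: int = 1000

    def effective_time(self, t: float) -> float:
        """Integral of the elongation scale factor from 0 to t."""
        if self.onset is None:
            return t
        if t <= self.onset:
            return t
        span = self.peak - self.onset
        if t >= self.peak:
            return self.onset + span / 2.0
        u = t - self.onset
        return self.onset + u - u * u / (2.0 * span)

    def tap_length(self, t: float) -> float:
        return self.r_tap * self.effective_time(t)

    def first_order(self, t: float) -> list[tuple[float, float]]:
        """(branch arc, final length) of every first-order lateral at day t."""
        ef = self.effective_time(t)
        tap = self.r_tap * ef
        out = []
        i = 0
        while i < self.nob:
            arc = self.basal + i * self.ln
            if arc + self.apical > tap:
                break
            e_emerge = (arc + self.apical) / self.r_tap
            out.append((arc, self.r_lateral * (ef - e_emerge)))
            i += 1
        return out

    def second_order_length(self, lateral_length: float, ef_emerge: float, ef_now: float) -> float:
        """Summed stub length on one first-order lateral."""
        reach = lateral_length - self.apical - self.basal
        if reach < 0:
            return 0.0
        n = int(math.floor(reach / self.ln)) + 1
        total = 0.0
        for j in range(n):
            arc = self.basal + j * self.ln
            ef_stub = ef_emerge + (arc + self.apical) / self.r_lateral
            total += min(self.stub_length, self.r_lateral * max(0.0, ef_now - ef_stub))
        return total

    def totals(self, t: float, second_order: bool = True) -> dict:
        """Lateral count, total length and top-5 cm share at day t."""
        ef = self.effective_time(t)
        laterals = self.first_order(t)
        total = self.tap_length(t)
        top5 = min(self.tap_length(t), 5.0)
        for arc, length in laterals:
            sub = length
            if second_order:
                ef_emerge = (arc + self.apical) / self.r_tap
                sub += self.second_order_length(length, ef_emerge, ef)
            total += sub
            if arc < 5.0:
                top5 += sub
        return {
            "n_first_order": len(laterals),
            "total_length": total,
            "top5_share": top5 / total if total > 0 else float("nan"),
            "tap_length": self.tap_length(t),
        }
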