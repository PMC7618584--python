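"""Method-agreement statistics for paired angle measurements.

Implements the evaluation toolkit used to compare two ways of measuring the
same quantity on the same images (e.g. automatic vs manual aFTA):

* intraclass correlation coefficient, by default ICC(2,1) — two-way
  random effects, absolute agreement, single measurement — with the
  standard F-based confidence interval, plus the usual interpretation
  bands (poor < 0.5 <= moderate < 0.75 <= good < 0.9 <= excellent);
* mean absolute difference (MAD) with the SD of the absolute differences;
* Bland-Altman bias, SD of the signed differences and 95% limits of
  agreement (bias +/- 1.96 * SD);
* the percentage of measurements inside a clinical acceptability band.

All SDs use the sample (n-1) denominator.  Human-readable reports round
half-up to one decimal; machine outputs keep full precision.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
from scipy.stats import f as f_dist

__all__ = [
    "PairedMeasurements",
    "AgreementReport",
    "BlandAltmanResult",
    "icc_agreement",
    "interpret_icc",
    "mad",
    "bland_altman",
    "pct_within_range",
    "build_report",
    "round_half_up",
    "LOA_MULTIPLIER",
]

#: Conventional limits-of-agreement multiplier (95% under normality).
LOA_MULTIPLIER = 1.96


@dataclass
class PairedMeasurements:
    """Two paired measurement series over the same images.

    Method A is conventionally the automatic system, method B the manual or
    clinical reference; signed differences are taken A minus B by default.
    """

    ids: Sequence[str]
    a_deg: np.ndarray
    b_deg: np.ndarray

    def __post_init__(self) -> None:
        self.a_deg = np.asarray(self.a_deg, dtype=float).ravel()
        self.b_deg = np.asarray(self.b_deg, dtype=float).ravel()
        self.ids = list(self.ids)
        if not (len(self.ids) == self.a_deg.size == self.b_deg.size):
            raise ValueError("ids, a_deg and b_deg must have equal length")
        if self.a_deg.size < 2:
            raise ValueError("need at least 2 pairs")
        if not (np.all(np.isfinite(self.a_deg)) and np.all(np.isfinite(self.b_deg))):
            raise ValueError("non-finite measurement")

    @property
    def n(self) -> int:
        return int(self.a_deg.size)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero at ``ndigits`` decimals (report style)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _anova_mean_squares(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float, int, int]:
    """Two-way ANOVA mean squares for an n x k table of ratings.

    Returns (MSR, MSC, MSE, n, k): rows = subjects, columns = raters/methods.
    """
    y = np.column_stack([a, b])
    n, k = y.shape
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    ss_total = float(np.sum((y - grand) ** 2))
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse, n, k


def icc_agreement(p: PairedMeasurements, ci_level: float = 0.95,
                  form: str = "icc2") -> tuple[float, float, float]:
    """Intraclass correlation between the two methods, with CI.

    ``form`` selects the single-measurement ICC variant:

    * ``"icc2"`` (default): two-way random effects, absolute agreement —
      sensitive to a systematic offset between the methods;
    * ``"icc3"``: two-way mixed, consistency — ignores a constant offset;
    * ``"icc1"``: one-way random effects.

    Returns ``(icc, ci_low, ci_high)`` with the F-based interval at
    ``ci_level``.  Raises ``ValueError`` when the ICC is undefined
    (no variance anywhere in the two-way table).
    """
    if not 0.0 < ci_level < 1.0:
        raise ValueError("ci_level must be in (0, 1)")
    msr, msc, mse, n, k = _anova_mean_squares(p.a_deg, p.b_deg)
    if max(msr, msc, mse) <= 0.0:
        raise ValueError("ICC undefined: all ratings identical (zero variance)")
    alpha = 1.0 - ci_level

    if form == "icc2":
        icc = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
        if mse <= 1e-14 * max(msr, msc):
            # error-free ratings: the F interval degenerates onto the point
            return float(icc), float(icc), float(icc)
        # Satterthwaite df for the absolute-agreement interval
        num = (k - 1) * (n - 1) * (
            k * icc * (msc / mse) + n * (1 + (k - 1) * icc) - k * icc) ** 2
        den = ((n - 1) * k**2 * icc**2 * (msc / mse) ** 2
               + (n * (1 + (k - 1) * icc) - k * icc) ** 2)
        v = num / den
        f_l = f_dist.ppf(1 - alpha / 2, n - 1, v)
        f_u = f_dist.ppf(1 - alpha / 2, v, n - 1)
        lo = (n * (msr - f_l * mse)
              / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr))
        hi = (n * (f_u * msr - mse)
              / (k * msc + (k * n - k - n) * mse + n * f_u * msr))
    elif form == "icc3":
        icc = (msr - mse) / (msr + (k - 1) * mse)
        if mse <= 1e-14 * max(msr, msc):
            return float(icc), float(icc), float(icc)
        fstat = msr / mse
        f_l = fstat / f_dist.ppf(1 - alpha / 2, n - 1, (n - 1) * (k - 1))
        f_u = fstat * f_dist.ppf(1 - alpha / 2, (n - 1) * (k - 1), n - 1)
        lo = (f_l - 1) / (f_l + k - 1)
        hi = (f_u - 1) / (f_u + k - 1)
    elif form == "icc1":
        y = np.column_stack([p.a_deg, p.b_deg])
        grand = y.mean()
        row_means = y.mean(axis=1)
        ss_rows = k * float(np.sum((row_means - grand) ** 2))
        ss_within = float(np.sum((y - row_means[:, None]) ** 2))
        msb = ss_rows / (n - 1)
        msw = ss_within / (n * (k - 1))
        if max(msb, msw) <= 0.0:
            raise ValueError("ICC undefined: all ratings identical")
        icc = (msb - msw) / (msb + (k - 1) * msw)
        if msw <= 1e-14 * msb:
            return float(icc), float(icc), float(icc)
        fstat = msb / msw
        f_l = fstat / f_dist.ppf(1 - alpha / 2, n - 1, n * (k - 1))
        f_u = fstat * f_dist.ppf(1 - alpha / 2, n * (k - 1), n - 1)
        lo = (f_l - 1) / (f_l + k - 1)
        hi = (f_u - 1) / (f_u + k - 1)
    else:
        raise ValueError(f"unknown ICC form {form!r}; use icc1, icc2 or icc3")

    lo = float(np.clip(lo, -1.0, 1.0)) if math.isfinite(lo) else -1.0
    hi = float(np.clip(hi, -1.0, 1.0)) if math.isfinite(hi) else 1.0
    return float(icc), lo, hi


def interpret_icc(icc: float) -> str:
    """Interpretation band: poor < 0.5 <= moderate < 0.75 <= good < 0.9 <= excellent."""
    if not math.isfinite(icc):
        raise ValueError("icc must be finite")
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc < 0.9:
        return "good"
    return "excellent"


def mad(p: PairedMeasurements) -> tuple[float, float]:
    """Mean absolute difference and the sample SD of the absolute differences."""
    d = np.abs(p.a_deg - p.b_deg)
    return float(d.mean()), float(d.std(ddof=1))


@dataclass
class BlandAltmanResult:
    bias_deg: float
    sd_deg: float
    loa_halfwidth_deg: float
    diffs: np.ndarray   # signed differences, per pair
    means: np.ndarray   # per-pair means (the Bland-Altman x axis)


def bland_altman(p: PairedMeasurements,
                 direction: str = "a_minus_b") -> BlandAltmanResult:
    """Bland-Altman bias, SD of signed differences and limits of agreement.

    ``direction`` is "a_minus_b" (default) or "b_minus_a".  The 95% limits
    of agreement are bias +/- 1.96 * SD; the half-width 1.96 * SD is
    returned directly.
    """
    if direction == "a_minus_b":
        d = p.a_deg - p.b_deg
    elif direction == "b_minus_a":
        d = p.b_deg - p.a_deg
    else:
        raise ValueError("direction must be 'a_minus_b' or 'b_minus_a'")
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias_deg=float(d.mean()),
        sd_deg=sd,
        loa_halfwidth_deg=LOA_MULTIPLIER * sd,
        diffs=d,
        means=(p.a_deg + p.b_deg) / 2.0,
    )


def pct_within_range(values: Sequence[float], lo: float, hi: float) -> float:
    """Percentage of values inside [lo, hi], inclusive at both ends."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    return 100.0 * float(np.count_nonzero((v >= lo) & (v <= hi))) / v.size


@dataclass
class AgreementReport:
    """Full agreement summary for one paired measurement set."""

    n: int
    icc: float
    icc_ci_low: float
    icc_ci_high: float
    icc_band: str
    mad_deg: float
    mad_sd_deg: float
    ba_bias_deg: float
    ba_sd_deg: float
    ba_loa_halfwidth_deg: float
    pct_acceptable_a: float
    pct_acceptable_b: float

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), **kwargs)

    @classmethod
    def from_json(cls, s: str) -> "AgreementReport":
        return cls(**json.loads(s))

    def format_table(self, ci_level: float = 0.95) -> str:
        """One-decimal, half-up rounded text summary in the conventional
        four-row agreement-table layout."""
        r1 = round_half_up
        pct = int(round(ci_level * 100))
        lines = [
            f"ICC ({pct}% CI)            "
            f"{self.icc:.2f} ({self.icc_ci_low:.2f}-{self.icc_ci_high:.2f})"
            f" [{self.icc_band}]",
            f"MAD (SD)                {r1(self.mad_deg)}° (±{r1(self.mad_sd_deg)}°)",
            f"BA bias (SD)            {r1(self.ba_bias_deg)}° (±{r1(self.ba_sd_deg)}°)",
            f"BA limits of agreement  ±{r1(self.ba_loa_halfwidth_deg)}°",
        ]
        return "\n".join(lines)


def build_report(p: PairedMeasurements,
                 acceptable_range: tuple[float, float] = (2.4, 7.2),
                 ci_level: float = 0.95,
                 icc_form: str = "icc2",
                 direction: str = "a_minus_b") -> AgreementReport:
    """Compute the full agreement report for one paired measurement set."""
    if p.n < 3:
        raise ValueError("need at least 3 pairs for a full report")
    icc, lo, hi = icc_agreement(p, ci_level=ci_level, form=icc_form)
    mad_deg, mad_sd = mad(p)
    ba = bland_altman(p, direction=direction)
    lo_r, hi_r = acceptable_range
    return AgreementReport(
        n=p.n,
        icc=icc, icc_ci_low=lo, icc_ci_high=hi, icc_band=interpret_icc(icc),
        mad_deg=mad_deg, mad_sd_deg=mad_sd,
        ba_bias_deg=ba.bias_deg, ba_sd_deg=ba.sd_deg,
        ba_loa_halfwidth_deg=ba.loa_halfwidth_deg,
        pct_acceptable_a=pct_within_range(p.a_deg, lo_r, hi_r),
        pct_acceptable_b=pct_within_range(p.b_deg, lo_r, hi_r),
    )
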