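"""Agreement and accuracy statistics for method comparison.

Implements the standard method-comparison toolbox for paired biometry:
per-label Dice overlap between two segmentations, Pearson correlation,
Bland–Altman mean difference with 95% limits of agreement, intraclass
correlation ICC(2,1) (two-way random effects, absolute agreement, single
measurement — the standard form for method comparison), and correlation of
errors against a covariate such as gestational age.

The difference direction is everywhere ``test − reference`` (automatic −
manual), so an under-reading algorithm yields negative mean differences.
Limits of agreement use the conventional large-sample 1.96 multiplier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

from .errors import ConstantInputError
from .mask_io import SegmentationVolume

__all__ = [
    "PairedMeasurements",
    "AgreementStats",
    "DiceResult",
    "dice",
    "agreement",
    "error_vs_covariate",
]

LOA_MULTIPLIER = 1.96


@dataclass
class PairedMeasurements:
    """Paired reference (manual) and test (automatic) measurements."""

    case_ids: list
    reference_mm: np.ndarray
    test_mm: np.ndarray
    covariate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.reference_mm = np.asarray(self.reference_mm, dtype=float)
        self.test_mm = np.asarray(self.test_mm, dtype=float)
        if self.covariate is not None:
            self.covariate = np.asarray(self.covariate, dtype=float)
        n = len(self.reference_mm)
        if n < 2 or len(self.test_mm) != n or len(self.case_ids) != n:
            raise ValueError("paired sequences must have equal length >= 2")
        if self.covariate is not None and len(self.covariate) != n:
            raise ValueError("covariate length must match pairs")
        arrays = [self.reference_mm, self.test_mm]
        if self.covariate is not None:
            arrays.append(self.covariate)
        if any(np.isnan(a).any() for a in arrays):
            raise ValueError("missing values are not allowed within pairs")

    def __len__(self) -> int:
        return len(self.reference_mm)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PairedMeasurements":
        cov = df["ga_weeks"].to_numpy() if "ga_weeks" in df.columns else None
        return cls(
            case_ids=list(df["case_id"]),
            reference_mm=df["reference_mm"].to_numpy(),
            test_mm=df["test_mm"].to_numpy(),
            covariate=cov,
        )


@dataclass(frozen=True)
class AgreementStats:
    """Pearson/Bland–Altman/ICC summary of one paired comparison.

    ``r_undefined`` is set (with NaN r, p and ICC) when either sequence is
    constant; the mean difference and limits of agreement are still valid.
    """

    pearson_r: float
    p_value: float
    mean_difference_mm: float
    loa_low_mm: float
    loa_high_mm: float
    icc: float
    n: int
    r_undefined: bool = False

    def as_dict(self) -> dict:
        return {
            "pearson_r": self.pearson_r,
            "p_value": self.p_value,
            "mean_difference_mm": self.mean_difference_mm,
            "loa_low_mm": self.loa_low_mm,
            "loa_high_mm": self.loa_high_mm,
            "icc": self.icc,
            "n": self.n,
        }


@dataclass(frozen=True)
class DiceResult:
    """Per-label Dice coefficients of two segmentations of the same grid."""

    per_label: dict[int, float]
    mean: float
    sd: float
    ventricles_pooled: float | None = None


def _dice_sets(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        return 1.0
    inter = int(np.count_nonzero(a & b))
    return 2.0 * inter / (na + nb)


def dice(a: SegmentationVolume, b: SegmentationVolume) -> DiceResult:
    """Per-label Dice ``2|A∩B| / (|A|+|B|)`` between two volumes.

    By convention Dice is 1 when a label is empty in both volumes and 0 when
    it is empty in exactly one.  The two lateral ventricles are additionally
    pooled into a single foreground set, mirroring how ventricular overlap
    is usually reported.
    """
    if a.labels.shape != b.labels.shape:
        raise ValueError(
            f"volume shapes differ: {a.labels.shape} vs {b.labels.shape}"
        )
    if a.schema != b.schema:
        raise ValueError("volumes use different label schemas")
    per_label = {
        int(lab): _dice_sets(a.labels == lab, b.labels == lab)
        for lab in a.schema.labels
    }
    values = np.array(list(per_label.values()))
    lv, rv = a.schema.left_ventricle, a.schema.right_ventricle
    pooled = _dice_sets(
        (a.labels == lv) | (a.labels == rv), (b.labels == lv) | (b.labels == rv)
    )
    return DiceResult(
        per_label=per_label,
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)),
        ventricles_pooled=pooled,
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("correlation undefined for constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _icc21(reference: np.ndarray, test: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater."""
    n = len(reference)
    long = pd.DataFrame(
        {
            "target": np.repeat(np.arange(n), 2),
            "rater": np.tile(["reference", "test"], n),
            "rating": np.column_stack([reference, test]).ravel(),
        }
    )
    table = pg.intraclass_corr(
        data=long, targets="target", raters="rater", ratings="rating"
    )
    # the two-way random / absolute agreement / single-rater row is labelled
    # "ICC2" or "ICC(A,1)" depending on the pingouin release
    row = table.loc[table["Type"].isin(["ICC2", "ICC(A,1)"]), "ICC"]
    return float(row.iloc[0])


def agreement(pairs: PairedMeasurements) -> AgreementStats:
    """Pearson r, Bland–Altman mean difference ± 1.96 SD limits, and ICC(2,1).

    Differences are ``test − reference``.  With an all-constant input the
    correlation (and ICC) are undefined; MD and limits are still returned
    with ``r_undefined=True``.
    """
    if len(pairs) < 3:
        raise ValueError(f"agreement needs n >= 3 pairs, got {len(pairs)}")
    diffs = pairs.test_mm - pairs.reference_mm
    md = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    loa_low, loa_high = md - LOA_MULTIPLIER * sd, md + LOA_MULTIPLIER * sd
    try:
        r, p = _pearson(pairs.reference_mm, pairs.test_mm)
        icc = _icc21(pairs.reference_mm, pairs.test_mm)
        undefined = False
    except ConstantInputError:
        r = p = icc = float("nan")
        undefined = True
    return AgreementStats(
        pearson_r=r,
        p_value=p,
        mean_difference_mm=md,
        loa_low_mm=loa_low,
        loa_high_mm=loa_high,
        icc=icc,
        n=len(pairs),
        r_undefined=undefined,
    )


def error_vs_covariate(pairs: PairedMeasurements) -> tuple[float, float]:
    """Pearson correlation between (test − reference) and the covariate.

    Used to check that measurement error does not drift with gestational
    age; returns ``(r, two-sided p)``.
    """
    if pairs.covariate is None:
        raise ValueError("pairs carry no covariate")
    if len(pairs) < 3:
        raise ValueError(f"correlation needs n >= 3 pairs, got {len(pairs)}")
    return _pearson(pairs.test_mm - pairs.reference_mm, pairs.covariate)
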