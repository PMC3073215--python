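"""HER2/CEP17 scoring: dot-to-nucleus assignment, per-nucleus ratios, case call.

Clinical convention: within each nucleus count HER2 (red) and CEP17
(green) signals, form the ratio red/green, average the ratio over up to 60
nuclei, and classify the case — a mean ratio above 2.2 denotes
amplification, below 1.8 a normal (non-amplified) state, and the closed
band [1.8, 2.2] is equivocal and needs further investigation.

Nuclei without any CEP17 signal are excluded from the average (the ratio
is undefined, and at least one centromere-17 copy per nucleus is
biologically expected).  The case mean is the mean of per-nucleus ratios,
not the ratio of summed counts; the latter is available as an option
because the two differ under heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nuclei import NucleusLabelMap

__all__ = [
    "DotRecord",
    "NucleusScore",
    "CaseScore",
    "UnscorableCaseError",
    "assign_dots",
    "nucleus_scores",
    "case_score",
    "classify",
    "estimate_count",
]

AMPLIFIED = "amplified"
EQUIVOCAL = "equivocal"
NON_AMPLIFIED = "non_amplified"


class UnscorableCaseError(RuntimeError):
    """No nucleus yields a defined HER2/CEP17 ratio."""

    def __init__(self, message: str, qc_warnings: list[str] | None = None):
        super().__init__(message)
        self.qc_warnings = qc_warnings or []


@dataclass
class DotRecord:
    """One detected probe signal.

    ``est_count`` is 1 unless the naive area-based overlap estimator is
    enabled; ``nucleus_id`` is None for dots outside every nucleus, which
    are excluded from scoring.
    """

    channel: str
    centroid: tuple[float, float]
    area: int
    nucleus_id: int | None = None
    est_count: int = 1

    def __post_init__(self) -> None:
        if self.channel not in ("red", "green"):
            raise ValueError(f"channel must be 'red' or 'green', got {self.channel!r}")
        if self.est_count < 1:
            raise ValueError("est_count must be >= 1")


@dataclass(frozen=True)
class NucleusScore:
    nucleus_id: int
    red_count: int
    green_count: int
    ratio: float | None  # None marks an excluded nucleus (no green signal)

    @property
    def excluded(self) -> bool:
        return self.ratio is None


@dataclass
class CaseScore:
    mean_ratio: float
    n_nuclei_used: int
    status: str
    max_cells: int = 60
    method: str | None = None
    qc_warnings: list[str] = field(default_factory=list)


def classify(ratio: float) -> str:
    """Map a mean HER2/CEP17 ratio onto the 1.8/2.2 decision bands.

    Strictly above 2.2 is amplified, strictly below 1.8 non-amplified,
    and the closed interval [1.8, 2.2] is equivocal.
    """
    if ratio < 0:
        raise ValueError("ratio must be nonnegative")
    if ratio > 2.2:
        return AMPLIFIED
    if ratio < 1.8:
        return NON_AMPLIFIED
    return EQUIVOCAL


def assign_dots(dots: list[DotRecord], nuclei: NucleusLabelMap) -> list[DotRecord]:
    """Set each dot's nucleus id from the label under its centroid pixel.

    Assignment is by centroid membership: the centroid is rounded to the
    nearest pixel and looked up in the label image.  Label 0 maps to
    ``None`` (outside every nucleus).
    """
    labels = nuclei.labels
    for dot in dots:
        r = int(round(dot.centroid[0]))
        c = int(round(dot.centroid[1]))
        if not (0 <= r < labels.shape[0] and 0 <= c < labels.shape[1]):
            raise ValueError(f"dot centroid {dot.centroid} outside image bounds")
        lab = int(labels[r, c])
        dot.nucleus_id = lab if lab > 0 else None
    return dots


def nucleus_scores(
    dots: list[DotRecord], nuclei: NucleusLabelMap
) -> list[NucleusScore]:
    """Per-nucleus red/green counts and ratios (summing ``est_count``)."""
    red = {f.label_id: 0 for f in nuclei.features}
    green = {f.label_id: 0 for f in nuclei.features}
    for dot in dots:
        if dot.nucleus_id is None or dot.nucleus_id not in red:
            continue
        if dot.channel == "red":
            red[dot.nucleus_id] += dot.est_count
        else:
            green[dot.nucleus_id] += dot.est_count
    scores = []
    for f in nuclei.features:
        g = green[f.label_id]
        r = red[f.label_id]
        ratio = (r / g) if g >= 1 else None
        scores.append(
            NucleusScore(nucleus_id=f.label_id, red_count=r, green_count=g, ratio=ratio)
        )
    return scores


def case_score(
    scores: list[NucleusScore],
    max_cells: int = 60,
    *,
    method: str | None = None,
    qc_warnings: list[str] | None = None,
    ratio_of_sums: bool = False,
) -> CaseScore:
    """Average per-nucleus ratios over the first ``max_cells`` scorable nuclei.

    Nuclei are taken in ``nucleus_id`` order; excluded nuclei (no green
    signal) are skipped.  ``ratio_of_sums=True`` replaces the mean of
    ratios by sum(red)/sum(green) over the same nuclei.  With zero
    scorable nuclei an :class:`UnscorableCaseError` is raised carrying the
    QC context.
    """
    qc = list(qc_warnings or [])
    usable = sorted(
        (s for s in scores if s.ratio is not None), key=lambda s: s.nucleus_id
    )[:max_cells]
    if not usable:
        raise UnscorableCaseError(
            "unscorable case: no nucleus with a defined HER2/CEP17 ratio",
            qc_warnings=qc,
        )
    if len(usable) < max_cells:
        qc.append(
            f"only {len(usable)} scorable nuclei available (target {max_cells})"
        )
    if ratio_of_sums:
        mean = float(sum(s.red_count for s in usable)) / float(
            sum(s.green_count for s in usable)
        )
    else:
        mean = float(np.mean([s.ratio for s in usable]))
    return CaseScore(
        mean_ratio=mean,
        n_nuclei_used=len(usable),
        status=classify(mean),
        max_cells=max_cells,
        method=method,
        qc_warnings=qc,
    )


def estimate_count(dot_area: float, reference_area: float) -> int:
    """Naive area-based copy estimate for merged dots.

    Overlapping signals (typically red) merge into one component; dividing
    its area by the median single-dot area and rounding (half up, floored
    at 1) gives a crude copy estimate.  This is a flagged extension, off
    by default — proper separation of merged dots needs dedicated
    post-processing.
    """
    if reference_area <= 0:
        raise ValueError("reference_area must be positive")
    return max(1, int(np.floor(dot_area / reference_area + 0.5)))
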