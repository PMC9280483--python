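"""Scikit-learn-style estimators wrapping the MSI-calling pipeline.

:class:`PeakCaller` is a transformer turning repeat-length histograms
into filtered peak sets.  :class:`MSIClassifier` is a paired-sample
classifier: ``fit`` grid-searches the peak-discovery hyperparameters
against PCR truth (the ``diff`` loss), ``predict`` labels tumor/normal
histogram pairs MSI-H or MSI-L.  Both compose with sklearn utilities
(`clone`, `get_params`/`set_params`), though the samples they operate on
are domain objects rather than numeric feature matrices.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .calling import (
    DEFAULT_MIN_READS,
    MarkerCall,
    PatientCall,
    classify_patient,
    compare_marker,
)
from .histograms import LengthHistogram
from .peaks import (
    RH_TOLERANCE,
    Hyperparameters,
    Peak,
    PeakSet,
    detect_candidate_peaks,
    pad_and_densify,
    relative_heights,
    smooth,
)
from .tuning import (
    DEFAULT_SMOOTHING_OPTIONS,
    DEFAULT_THRESHOLDS,
    PCRTruth,
    TuningResult,
    diff_loss,
)


class PeakCaller(TransformerMixin, BaseEstimator):
    """Transform repeat-length histograms into filtered peak sets.

    Parameters
    ----------
    smoothing : bool, default True
        Apply the centered window-3 moving average before detection.
    r_h : float, default 0.2
        Relative-height threshold; candidates below it are discarded as
        technical noise (stutter shoulders, stray reads).
    denominator_mode : str, default "mean_nonzero_bins"
        Normalization for relative height; see :mod:`msipeaks.peaks`.
    """

    def __init__(
        self,
        smoothing: bool = True,
        r_h: float = 0.2,
        denominator_mode: str = "mean_nonzero_bins",
    ):
        self.smoothing = smoothing
        self.r_h = r_h
        self.denominator_mode = denominator_mode

    def fit(self, X: Iterable[LengthHistogram] | None = None, y=None) -> "PeakCaller":
        """Validate parameters; the transform itself is stateless."""
        self.hyperparameters_ = Hyperparameters(
            smoothing=self.smoothing,
            r_h=self.r_h,
            denominator_mode=self.denominator_mode,
        )
        return self

    def call_histogram(self, histogram: LengthHistogram) -> PeakSet:
        """Densify -> (smooth) -> detect local maxima -> threshold on rh."""
        check_is_fitted(self, "hyperparameters_")
        hp = self.hyperparameters_
        series, offset = pad_and_densify(histogram)
        empty = PeakSet(
            sample_id=histogram.sample_id,
            tissue=histogram.tissue,
            marker_name=histogram.marker_name,
            peaks=[],
            hyperparameters=hp,
            total_reads=histogram.total,
        )
        if offset is None:
            return empty
        if hp.smoothing:
            series = smooth(series)
            offset -= 1
        candidates = detect_candidate_peaks(series)
        if not candidates:
            return empty
        annotated = relative_heights(candidates, series, hp.denominator_mode)
        peaks = [
            Peak(position=idx + offset, height=h, relative_height=rh)
            for idx, h, rh in annotated
            if rh >= hp.r_h - RH_TOLERANCE
        ]
        empty.peaks = peaks
        return empty

    def transform(self, X: Iterable[LengthHistogram]) -> list[PeakSet]:
        return [self.call_histogram(h) for h in X]


class MSIClassifier(BaseEstimator):
    """Tumor/normal MSI status caller with grid-search tuning.

    One "sample" for :meth:`predict` is a pair
    ``(tumor_histograms, normal_histograms)`` of per-marker
    :class:`LengthHistogram` lists.  :meth:`fit` takes training
    histograms and a :class:`PCRTruth` table and selects the
    (smoothing, r_h) combination minimizing the ``diff`` loss; an
    unfitted classifier predicts with its constructor hyperparameters.

    Parameters
    ----------
    smoothing, r_h, denominator_mode
        Peak-discovery settings used when the classifier is not fitted
        (defaults are the tuned operating point: smoothing on, r_h 0.2).
    min_reads : int, default 20
        Minimum anchor-matched reads per marker per sample; below it the
        marker is uninformative.
    thresholds, smoothing_options
        Grid searched by :meth:`fit`; default 0.1..3.0 x {on, off}.
    tissues
        Which tissues' histograms enter the loss (default both).
    """

    def __init__(
        self,
        smoothing: bool = True,
        r_h: float = 0.2,
        denominator_mode: str = "mean_nonzero_bins",
        min_reads: int = DEFAULT_MIN_READS,
        thresholds: Sequence[float] | None = None,
        smoothing_options: Sequence[bool] | None = None,
        tissues: Sequence[str] | None = None,
    ):
        self.smoothing = smoothing
        self.r_h = r_h
        self.denominator_mode = denominator_mode
        self.min_reads = min_reads
        self.thresholds = thresholds
        self.smoothing_options = smoothing_options
        self.tissues = tissues

    # -- tuning -------------------------------------------------------

    def fit(self, X: Sequence[LengthHistogram], y: PCRTruth) -> "MSIClassifier":
        """Grid-search smoothing x threshold minimizing diff_loss on (X, y).

        Ties break toward lower diff, then smoothing on, then the lowest
        threshold (lower thresholds retain sensitivity to minor alleles).
        """
        histograms = list(X)
        if not histograms:
            raise ValueError("empty training set")
        if not isinstance(y, PCRTruth):
            y = PCRTruth(dict(y))
        if self.tissues is not None:
            y = y.restrict_tissues(self.tissues)
        if not y.entries:
            raise ValueError("PCR truth has no entries for the requested tissues")
        thresholds = tuple(self.thresholds or DEFAULT_THRESHOLDS)
        smoothing_options = tuple(
            DEFAULT_SMOOTHING_OPTIONS
            if self.smoothing_options is None
            else self.smoothing_options
        )
        if not thresholds:
            raise ValueError("empty threshold grid")

        grid: list[tuple[Hyperparameters, float]] = []
        for smoothing in smoothing_options:
            for r_h in thresholds:
                hp = Hyperparameters(
                    smoothing=smoothing,
                    r_h=r_h,
                    denominator_mode=self.denominator_mode,
                )
                caller = PeakCaller(**_hp_params(hp)).fit()
                counts = {h.key: len(caller.call_histogram(h)) for h in histograms}
                grid.append((hp, diff_loss(counts, y)))
        # tie-break: lowest diff, then smoothing on, then lowest threshold
        best_hp, best_diff = min(
            grid, key=lambda item: (item[1], not item[0].smoothing, item[0].r_h)
        )
        self.hyperparameters_ = best_hp
        self.best_diff_ = best_diff
        self.grid_ = grid
        self.tuning_result_ = TuningResult(grid=grid, best=best_hp, best_diff=best_diff)
        return self

    # -- calling ------------------------------------------------------

    def _effective_hyperparameters(self) -> Hyperparameters:
        if hasattr(self, "hyperparameters_"):
            return self.hyperparameters_
        return Hyperparameters(
            smoothing=self.smoothing,
            r_h=self.r_h,
            denominator_mode=self.denominator_mode,
        )

    def call_pair(
        self,
        tumor_histograms: Sequence[LengthHistogram],
        normal_histograms: Sequence[LengthHistogram],
        sample_id: str | None = None,
    ) -> PatientCall:
        """Full evidence for one patient: per-marker calls plus verdict.

        Tumor and normal histograms are matched by marker name; marker
        order follows the tumor list (the panel order in normal use).
        """
        hp = self._effective_hyperparameters()
        caller = PeakCaller(**_hp_params(hp)).fit()
        normal_by_marker = {h.marker_name: h for h in normal_histograms}
        missing = [
            h.marker_name
            for h in tumor_histograms
            if h.marker_name not in normal_by_marker
        ]
        if missing:
            raise ValueError(f"normal sample lacks histograms for markers {missing}")
        sid = sample_id or (
            tumor_histograms[0].sample_id if tumor_histograms else "sample"
        )
        marker_calls: list[MarkerCall] = []
        for tumor_hist in tumor_histograms:
            normal_hist = normal_by_marker[tumor_hist.marker_name]
            call = compare_marker(
                caller.call_histogram(tumor_hist),
                caller.call_histogram(normal_hist),
                min_reads=self.min_reads,
            )
            marker_calls.append(call)
        return classify_patient(marker_calls, sid)

    def predict(
        self,
        X: Sequence[tuple[Sequence[LengthHistogram], Sequence[LengthHistogram]]],
    ) -> np.ndarray:
        """MSI-H / MSI-L label per (tumor, normal) histogram pair."""
        return np.array(
            [self.call_pair(tumor, normal).status for tumor, normal in X],
            dtype=object,
        )


def _hp_params(hp: Hyperparameters) -> dict:
    return {
        "smoothing": hp.smoothing,
        "r_h": hp.r_h,
        "denominator_mode": hp.denominator_mode,
    }
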