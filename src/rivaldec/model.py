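"""High-level modelling interface: a decoder model fitted to a subject's
two runs, returning a results object with estimates, diagnostics and a
summary table.

:class:`BinocularRivalryDecoder` bundles the prepared localizer (BNR) and
rivalry (BR) inputs with the behavioral percept vector; :meth:`fit` trains
the network with the reiteration rule and scores it, returning
:class:`DecodingResults`.  Reliability assessment, ROI-count ablation and
distribution plots hang off the results object.  The
:meth:`BinocularRivalryDecoder.from_runs` constructor runs the full
pipeline (localize -> extract -> prepare) from 4D arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import localizer as loc
from . import sigprep
from .decoder import TrainConfig, classify, decode_with_reiteration, train
from .paradigm import BehavioralLog, BlockDesign, behavioral_to_percept_vector
from .stats import (
    ReliabilityReport,
    binomial_pvalue,
    reliability_run,
    reliability_verdict,
    success_rate,
)

__all__ = ["BinocularRivalryDecoder", "DecodingResults", "SubjectExcluded"]


class SubjectExcluded(RuntimeError):
    """The localizer did not yield the minimum ROI configuration."""

    def __init__(self, exclusion):
        super().__init__(exclusion.reason)
        self.exclusion = exclusion


def ablation_order(roiset: loc.RoiSet) -> loc.RoiSet:
    """Order ROIs so every prefix is a valid decoding set: the minimum
    configuration first (best face-contrast ROI, best two house-contrast
    ROIs), then the remaining ROIs by peak t."""
    face = [r for r in roiset.rois if r.contrast == loc.FACE_GT_HOUSE]
    house = [r for r in roiset.rois if r.contrast == loc.HOUSE_GT_FACE]
    face.sort(key=lambda r: -r.peak_t)
    house.sort(key=lambda r: -r.peak_t)
    core = face[:1] + house[:2]
    rest = sorted(face[1:] + house[2:], key=lambda r: -r.peak_t)
    return loc.RoiSet(rois=core + rest, threshold_used=roiset.threshold_used,
                      metadata=dict(roiset.metadata))


class BinocularRivalryDecoder:
    """Decoding model for one subject.

    Parameters
    ----------
    bnr_inputs, br_inputs : PreparedInputs
        Outputs of the signal-preparation chain for the localizer and
        rivalry runs (same ROI set, same column order).
    percept_vector : PerceptVector
        Behavioral ground truth for the rivalry task time points.
    config : TrainConfig, optional
        Training/decoding operating points; defaults are the method's.
    """

    def __init__(self, bnr_inputs, br_inputs, percept_vector, config: TrainConfig | None = None,
                 roiset: loc.RoiSet | None = None):
        if bnr_inputs.task_matrix.shape[1] != br_inputs.task_matrix.shape[1]:
            raise ValueError("localizer and rivalry inputs must share the ROI set")
        if len(percept_vector.labels) != br_inputs.task_matrix.shape[0]:
            raise ValueError("percept vector length must match rivalry task points")
        self.bnr_inputs = bnr_inputs
        self.br_inputs = br_inputs
        self.percept_vector = percept_vector
        self.config = config or TrainConfig()
        self.roiset = roiset

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_runs(
        cls,
        bnr_volumes: np.ndarray,
        bnr_design: BlockDesign,
        br_volumes: np.ndarray,
        br_design: BlockDesign,
        behavioral_log: BehavioralLog,
        config: TrainConfig | None = None,
        fwhm_mm: float = 5.0,
        voxel_size_mm: float = 3.0,
        bold_delay_s: float = 6.0,
        br_z_offset: int = 7,
        n_rois: int | None = None,
        kmeans_seed: int = 0,
    ) -> "BinocularRivalryDecoder":
        """Build the model from raw 4D runs: localize ROIs on the smoothed
        localizer run, extract and prepare both runs' ROI time courses, and
        convert the behavioral log to a percept vector.

        Raises :class:`SubjectExcluded` when the localizer cannot supply the
        minimum ROI configuration.
        """
        mask = loc.package_mask(bnr_volumes.shape[:-1], n_slices=br_volumes.shape[2],
                                z_offset=br_z_offset)
        roiset, _ = loc.localize(bnr_volumes, bnr_design, fwhm_mm=fwhm_mm,
                                 voxel_size_mm=voxel_size_mm, mask=mask)
        if isinstance(roiset, loc.Exclusion):
            raise SubjectExcluded(roiset)
        roiset = ablation_order(roiset)
        if n_rois is not None:
            roiset = loc.RoiSet(rois=roiset.rois[:n_rois], threshold_used=roiset.threshold_used)
        bnr_tcs = sigprep.extract_timecourses(bnr_volumes, roiset, bnr_design, z_offset=0)
        br_tcs = sigprep.extract_timecourses(br_volumes, roiset, br_design, z_offset=br_z_offset)
        bnr_prep = sigprep.prepare_inputs(bnr_tcs, "BNR", bold_delay_s=bold_delay_s,
                                          kmeans_seed=kmeans_seed)
        br_prep = sigprep.prepare_inputs(br_tcs, "BR", bold_delay_s=bold_delay_s,
                                         kmeans_seed=kmeans_seed)
        pv = behavioral_to_percept_vector(behavioral_log, br_design)
        return cls(bnr_prep, br_prep, pv, config=config, roiset=roiset)

    # -- fitting ----------------------------------------------------------

    def fit(self, seed: int | None = None) -> "DecodingResults":
        """Train with restarts and the reiteration rule, decode the rivalry
        run, and score against the behavioral reports."""
        model, output, n_iter = decode_with_reiteration(
            self.bnr_inputs, self.br_inputs, self.config, seed=seed
        )
        report = success_rate(output.assignments, self.percept_vector.labels)
        report.p_value = binomial_pvalue(report.n_success, report.n_assigned)
        return DecodingResults(self, model, output, report, n_iter)

    def assess_reliability(self, n_rep: int = 1000, seed: int = 0,
                           val_mse: float | None = None):
        """Repeat train+classify ``n_rep`` times on the rivalry task signal
        and on the rest-block control, then evaluate the four-condition
        verdict.

        Does not require an accepted decoding fit: a subject without
        percept-locked signal never satisfies the unassigned-fraction rule,
        yet the reliability protocol still applies (and is what flags such a
        subject).  When ``val_mse`` is not given, one network is trained to
        supply the training-performance condition.

        Returns ``(ReliabilityReport, verdict_dict)``.
        """
        cfg = self.config

        def pipeline(matrix, rep_seed):
            ann = train(self.bnr_inputs.task_matrix, self.bnr_inputs.target_matrix,
                        cfg, seed=rep_seed)
            return classify(ann, matrix, cfg.margin)

        if val_mse is None:
            ref = train(self.bnr_inputs.task_matrix, self.bnr_inputs.target_matrix,
                        cfg, seed=seed)
            val_mse = ref.record.final_val_mse
        report = reliability_run(
            pipeline, self.br_inputs.task_matrix, self.br_inputs.rest_matrix,
            n_rep=n_rep, seed=seed,
        )
        verdict = reliability_verdict(report, n_rois=self.bnr_inputs.n_rois,
                                      model_val_mse=val_mse)
        return report, verdict

    def fit_roi_ablation(self, roi_counts=(3, 4, 5), seed: int | None = None) -> pd.DataFrame:
        """Refit using the top-3/4/5 ROI subsets (availability permitting)."""
        rows = []
        for k in roi_counts:
            if k > self.bnr_inputs.n_rois:
                continue
            sub = BinocularRivalryDecoder(
                self.bnr_inputs.subset(k), self.br_inputs.subset(k),
                self.percept_vector, self.config, roiset=self.roiset,
            )
            res = sub.fit(seed=seed)
            rows.append({"n_rois": k, "success_pct": res.report.success_pct,
                         "p_value": res.report.p_value,
                         "discarded_pct": res.report.discarded_pct})
        return pd.DataFrame(rows)


@dataclass
class DecodingResults:
    """Fit outcome: the accepted network, its rivalry-run classification,
    and the behavioral scoring."""

    model_spec: BinocularRivalryDecoder
    ann: "AnnModel"
    classification: "ClassificationOutput"
    report: "SuccessReport"
    n_reiterations: int
    reliability: ReliabilityReport | None = field(default=None)

    # -- headline numbers --------------------------------------------------

    @property
    def success_pct(self) -> float:
        return self.report.success_pct

    @property
    def p_value(self) -> float:
        return self.report.p_value

    @property
    def discarded_pct(self) -> float:
        return self.report.discarded_pct

    @property
    def val_mse(self) -> float:
        return self.ann.record.final_val_mse

    def summary(self) -> str:
        r = self.report
        lines = [
            "Binocular rivalry decoding results",
            "==================================",
            f"ROIs (input columns):      {self.model_spec.bnr_inputs.n_rois}",
            f"Validation MSE:            {self.val_mse:.4f} (threshold {self.model_spec.config.mse_threshold})",
            f"Reiterations used:         {self.n_reiterations}",
            f"Rivalry task time points:  {r.n_task}",
            f"Assigned / scored points:  {r.n_assigned}",
            f"Discarded (unassigned) %:  {r.discarded_pct:.1f}",
            f"Success %:                 {r.success_pct:.1f}",
            f"Binomial p (one-sided):    {r.p_value:.4g}",
        ]
        if self.reliability is not None and self.reliability.verdict is not None:
            v = self.reliability.verdict
            lines += [
                "Reliability verdict:",
                f"  >=3 ROIs:                        {v['rois_present']}",
                f"  training MSE < 0.02:             {v['training_mse_ok']}",
                f"  balanced & leptokurtic/normal:   {v['balanced_leptokurtic_task']}",
                f"  tighter/more symmetric vs rest:  {v['task_tighter_than_rest']}",
                f"  overall:                         {v['overall']}",
            ]
        return "\n".join(lines)

    # -- reliability -------------------------------------------------------

    def assess_reliability(self, n_rep: int = 1000, seed: int = 0) -> dict:
        """Repeat train+classify ``n_rep`` times on task and rest-control
        inputs, then evaluate the four-condition verdict using this fit's
        validation MSE."""
        report, verdict = self.model_spec.assess_reliability(
            n_rep=n_rep, seed=seed, val_mse=self.val_mse
        )
        self.reliability = report
        return verdict

    # -- plotting ----------------------------------------------------------

    def plot_reliability_histograms(self, ax=None):
        """Bar histograms of the per-repetition house percentages, task vs
        rest control."""
        import matplotlib.pyplot as plt

        if self.reliability is None:
            raise ValueError("run assess_reliability first")
        if ax is None:
            _, ax = plt.subplots(2, 1, sharex=True, figsize=(6, 6))
        bins = np.linspace(0, 100, 41)
        ax[0].hist(self.reliability.task_fractions, bins=bins, color="tab:blue")
        ax[0].set_title("task signal")
        ax[1].hist(self.reliability.rest_fractions, bins=bins, color="tab:orange")
        ax[1].set_title("rest-block control")
        ax[1].set_xlabel("house % of assigned time points")
        return ax
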