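"""Model/Results interface over the full analysis pipeline.

:class:`RunningSessionModel` wraps one session; ``fit()`` runs cleaning,
windowing, feature extraction, regime clustering and recurrence analysis
and returns a :class:`RunningSessionResults` carrying the estimates and a
``summary()`` table.  :class:`CohortModel` does the same across sessions,
adding the regime-frequency vs. VO2max correlations and the section-wise
group tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import clustering, features, preprocess, rqa, session_analysis, stationarity_acf
from .io_sessions import AlignedSegment, Session, UniformSeries, align_channels
from .preprocess import CleaningConfig

__all__ = [
    "PipelineConfig",
    "RunningSessionModel",
    "RunningSessionResults",
    "CohortModel",
    "CohortResults",
    "estimate_width_from_sessions",
]


def estimate_width_from_sessions(
    sessions: list, config: PipelineConfig | None = None
) -> stationarity_acf.WindowWidthEstimate:
    """Window-width calibration across whole sessions.

    Each session's heart rate is outlier-repaired on the raw samples and
    put on the uniform grid; the per-session ACF cutoff lags are then
    aggregated into one analysis-window width.
    """
    config = config or PipelineConfig()
    cl = config.cleaning
    series = []
    for sess in sessions:
        ch = preprocess.remove_outliers_zscore_raw(
            sess.channels["hr"], cl.zscore_threshold
        )
        clean = Session(
            session_id=sess.session_id, date=sess.date, age=sess.age,
            vo2max=sess.vo2max, channels={**sess.channels, "hr": ch},
            duration=sess.duration,
        )
        for seg in align_channels(clean, dt=config.dt, max_gap_s=cl.max_gap_s):
            series.append(UniformSeries(seg.t0, seg.dt, seg.hr))
    return stationarity_acf.estimate_window_width(
        series, detrend_order=config.detrend_order,
        max_lag_s=config.acf_max_lag_s, alpha=config.acf_alpha,
    )


@dataclass
class PipelineConfig:
    """Resolved configuration of the whole pipeline."""

    cleaning: CleaningConfig = field(default_factory=CleaningConfig)
    dt: float = 1.0
    window_width_s: float = 90.0  # canonical analysis window
    estimate_window: bool = False  # re-derive the width from this session's ACF
    acf_alpha: float = 0.05
    acf_max_lag_s: float = 300.0
    detrend_order: int = 1
    g: float = features.STANDARD_GRAVITY
    scaling_alpha: float = 3.0
    k: int = 4  # fixed number of regimes; None -> silhouette selection
    k_range: tuple = (2, 10)
    n_init: int = 10
    kmeans_tol: float = 1e-5
    rqa: rqa.RQAConfig = field(default_factory=rqa.RQAConfig)

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


@dataclass
class RunningSessionResults:
    """Everything the single-session pipeline estimates."""

    session_id: str
    config: PipelineConfig
    seed: int
    width_s: float
    segments: list  # retained intense-zone AlignedSegments
    window_features: pd.DataFrame  # includes the 'regime' column
    scaling: clustering.FeatureScaling
    cluster_model: clustering.ClusterModel
    sign_labels: dict
    silhouette: clustering.SilhouetteReport
    frequencies: session_analysis.SessionClusterSummary
    sections: list
    section_dets: dict
    rqa_result: rqa.RQAResult
    k_scores: dict | None = None
    width_estimate: stationarity_acf.WindowWidthEstimate | None = None

    @property
    def regime_labels(self) -> np.ndarray:
        return self.window_features["regime"].to_numpy()

    def centroids_unscaled(self) -> pd.DataFrame:
        raw = self.scaling.inverse(self.cluster_model.centroids)
        return pd.DataFrame(
            {
                "regime": [self.sign_labels[j] for j in range(self.cluster_model.k)],
                "delta_e": raw[:, 0],
                "delta_hr": raw[:, 1],
            }
        )

    def summary(self) -> str:
        freq = self.frequencies.frequencies
        cent = self.centroids_unscaled().set_index("regime")
        lines = [
            "Heartbeat-dynamics regime analysis",
            "=" * 50,
            f"session            {self.session_id}",
            f"analysis window    {self.width_s:.0f} s",
            f"windows            {len(self.window_features)}",
            f"clusters (k)       {self.cluster_model.k}",
            f"mean silhouette    {self.silhouette.mean:.3f}",
            f"scaling alpha      {self.scaling.alpha:.2f} "
            f"(coverage {self.scaling.coverage:.3f})",
            "-" * 50,
            "regime   frequency   <dE>      <dHR>",
        ]
        for lab in clustering.SIGN_LABELS:
            if lab in cent.index:
                lines.append(
                    f"{lab:6s}   {freq.get(lab, 0.0):9.3f}   "
                    f"{cent.loc[lab, 'delta_e']:+.3f}    "
                    f"{cent.loc[lab, 'delta_hr']:+.3f}"
                )
        lines.append("-" * 50)
        lines.append("section  " + "  ".join(f"{lab:>6s}" for lab in clustering.SIGN_LABELS)
                     + "     DET")
        for sec in self.sections:
            det = self.section_dets.get(sec.section)
            det_s = f"{det:.3f}" if det is not None else "  n/a"
            if sec.frequencies is None:
                lines.append(f"{sec.section:7s}  (no windows)")
            else:
                lines.append(
                    f"{sec.section:7s}  "
                    + "  ".join(f"{sec.frequencies[lab]:6.3f}"
                               for lab in clustering.SIGN_LABELS)
                    + f"   {det_s}"
                )
        return "\n".join(lines)


class RunningSessionModel:
    """Single running session -> heartbeat-dynamics regimes.

    Parameters
    ----------
    session : Session
        Raw multi-channel session (hr required; speed and altitude needed
        for the energy features).
    config : PipelineConfig, optional
    """

    def __init__(self, session: Session, config: PipelineConfig | None = None):
        self.session = session
        self.config = config or PipelineConfig()

    @classmethod
    def from_csv(cls, path, config: PipelineConfig | None = None):
        from .io_sessions import read_session_csv

        return cls(read_session_csv(path), config=config)

    # -- pipeline stages -------------------------------------------------

    def _clean_segments(self) -> list:
        cfg = self.config
        cl = cfg.cleaning
        # outlier repair happens on the raw sensor samples, before any
        # interpolation can smear a spike across the grid
        session = self.session
        hr_clean = preprocess.remove_outliers_zscore_raw(
            session.channels["hr"], cl.zscore_threshold
        )
        if hr_clean is not session.channels["hr"]:
            channels = dict(session.channels)
            channels["hr"] = hr_clean
            session = Session(
                session_id=session.session_id, date=session.date,
                age=session.age, vo2max=session.vo2max,
                channels=channels, duration=session.duration,
            )
        segs = align_channels(session, dt=cfg.dt, max_gap_s=cl.max_gap_s)
        cleaned = []
        z_offset = None
        for seg in segs:
            hr = seg.hr
            speed = seg.speed
            if speed is not None:
                try:
                    speed = preprocess.lowpass_speed(
                        UniformSeries(seg.t0, seg.dt, speed),
                        cl.butter_cutoff, cl.butter_order,
                    ).values
                except ValueError:
                    warnings.warn("segment too short to filter speed; left raw",
                                  stacklevel=2)
            alt = seg.altitude
            if alt is not None:
                if z_offset is None:
                    z_offset = alt[0]  # session start altitude
                alt = alt - z_offset
            cleaned.append(AlignedSegment(seg.t0, seg.dt, hr, speed, alt))
        return cleaned

    def _intense_segments(self, cleaned: list) -> list:
        cfg = self.config
        cl = cfg.cleaning
        hrmax = preprocess.hr_max_tanaka(self.session.age)
        out = []
        for seg in cleaned:
            _, runs = preprocess.restrict_to_intense_zone(
                UniformSeries(seg.t0, seg.dt, seg.hr), hrmax,
                cl.hr_zone_fraction, cl.min_segment_s,
            )
            for a, b in runs:
                out.append(
                    AlignedSegment(
                        seg.t0 + a * seg.dt, seg.dt, seg.hr[a:b],
                        seg.speed[a:b] if seg.speed is not None else None,
                        seg.altitude[a:b] if seg.altitude is not None else None,
                    )
                )
        return out

    def fit(self, seed: int = 0) -> RunningSessionResults:
        """Run the full pipeline and return the results object."""
        cfg = self.config
        cleaned = self._clean_segments()
        retained = self._intense_segments(cleaned)
        if not retained:
            raise ValueError("no analyzable segments: heart rate never sustained "
                             "the intense zone")

        width_estimate = None
        width = cfg.window_width_s
        if cfg.estimate_window:
            hr_all = [UniformSeries(s.t0, s.dt, s.hr) for s in cleaned]
            width_estimate = stationarity_acf.estimate_window_width(
                hr_all, detrend_order=cfg.detrend_order,
                max_lag_s=cfg.acf_max_lag_s, alpha=cfg.acf_alpha,
            )
            width = width_estimate.chosen_width

        energies = features.compute_energy_segments(retained, g=cfg.g)
        feats = features.window_features(retained, energies, width_s=width)
        if len(feats) < 8:
            raise ValueError("too few analysis windows for clustering")

        points, scaling = clustering.scale_features(
            feats["delta_e"], feats["delta_hr"], alpha=cfg.scaling_alpha
        )
        rng = np.random.default_rng(seed)
        k_scores = None
        if cfg.k is None:
            k, k_scores = clustering.select_k(
                points, range(cfg.k_range[0], cfg.k_range[1] + 1),
                tol=cfg.kmeans_tol, n_init=cfg.n_init,
                seed=int(rng.integers(2**31 - 1)),
            )
        else:
            k = cfg.k
        model = clustering.kmeans(points, k, tol=cfg.kmeans_tol,
                                  n_init=cfg.n_init,
                                  seed=int(rng.integers(2**31 - 1)))
        sil = clustering.silhouette(points, model.labels)
        model.mean_silhouette = sil.mean
        sign_labels = clustering.assign_sign_labels(model, scaling)

        feats = feats.copy()
        feats["cluster"] = model.labels
        feats["regime"] = [sign_labels[j] for j in model.labels]
        feats["independent"] = session_analysis.nonoverlapping_subset(
            feats["window_start_s"], width
        )

        freqs = session_analysis.cluster_frequencies(
            feats["regime"], session_id=self.session.session_id,
            date=self.session.date, vo2max=self.session.vo2max,
        )

        # analysis-domain HR: concatenated intense-zone series
        hr_concat = np.concatenate([s.hr for s in retained])
        section_dets = rqa.section_det(hr_concat, cfg.rqa)
        rqa_all = rqa.rqa_analyze(hr_concat, cfg.rqa)

        t_begin = retained[0].t0
        t_end = retained[-1].t0 + retained[-1].dt * retained[-1].n
        sections = session_analysis.section_frequencies(
            feats["window_start_s"].to_numpy() - t_begin,
            feats["regime"].to_numpy(), width, t_end - t_begin,
            dets=section_dets,
        )

        return RunningSessionResults(
            session_id=self.session.session_id,
            config=cfg,
            seed=seed,
            width_s=width,
            segments=retained,
            window_features=feats,
            scaling=scaling,
            cluster_model=model,
            sign_labels=sign_labels,
            silhouette=sil,
            frequencies=freqs,
            sections=sections,
            section_dets=section_dets,
            rqa_result=rqa_all,
            k_scores=k_scores,
            width_estimate=width_estimate,
        )


@dataclass
class CohortResults:
    summaries: list
    per_session: pd.DataFrame
    correlations: session_analysis.CorrelationReport | None
    session_results: list

    def summary(self) -> str:
        lines = [
            "Cohort heartbeat-dynamics summary",
            "=" * 60,
            self.per_session.to_string(index=False,
                                       float_format=lambda v: f"{v:.3f}"),
        ]
        if self.correlations is not None:
            lines.append("-" * 60)
            lines.append("regime frequency vs VO2max (Pearson):")
            for lab, (r, p, n) in self.correlations.per_label.items():
                lines.append(f"  {lab:4s}  r = {r:+.3f}   p = {p:.4f}   n = {n}")
        return "\n".join(lines)


class CohortModel:
    """A set of sessions from one subject, analysed with shared settings."""

    def __init__(self, sessions: list, config: PipelineConfig | None = None):
        if len(sessions) < 3:
            raise ValueError("need at least 3 sessions")
        self.sessions = sessions
        self.config = config or PipelineConfig()

    def fit(self, seed: int = 0) -> CohortResults:
        rng = np.random.default_rng(seed)
        summaries, results, rows = [], [], []
        for sess in self.sessions:
            try:
                res = RunningSessionModel(sess, self.config).fit(
                    seed=int(rng.integers(2**31 - 1))
                )
            except ValueError as exc:
                warnings.warn(f"session {sess.session_id!r} skipped: {exc}",
                              stacklevel=2)
                continue
            summaries.append(res.frequencies)
            results.append(res)
            rows.append(
                {
                    "session_id": sess.session_id,
                    "date": sess.date,
                    "vo2max": sess.vo2max,
                    **{f"freq_{lab}": res.frequencies.frequencies.get(lab, 0.0)
                       for lab in clustering.SIGN_LABELS},
                    "mean_silhouette": res.silhouette.mean,
                    "det_start": res.section_dets.get("start"),
                    "det_end": res.section_dets.get("end"),
                }
            )
        if len(summaries) < 3:
            raise ValueError("fewer than 3 sessions analysable")
        correlations = None
        n_vo2 = sum(s.vo2max is not None for s in summaries)
        if n_vo2 >= 3:
            correlations = session_analysis.correlate_vo2max(summaries)
        else:
            warnings.warn("not enough sessions with vo2max for correlation",
                          stacklevel=2)
        return CohortResults(
            summaries=summaries,
            per_session=pd.DataFrame(rows),
            correlations=correlations,
            session_results=results,
        )
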