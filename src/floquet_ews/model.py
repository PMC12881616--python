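"""Model/results interface for Floquet-multiplier stability analysis.

``FloquetDMD`` is constructed from a series or field plus the analysis
configuration; ``fit()`` runs the rolling period-lagged DMD, matches and
classifies the eigenvalue tracks and scans for a stability-threshold crossing,
returning a ``FloquetDMDResults`` carrying the estimates and diagnostics.

Example
-------
>>> from floquet_ews import FloquetDMD, simulate_pitchfork, PitchforkParams
>>> run = simulate_pitchfork(PitchforkParams(seed=3))
>>> res = FloquetDMD(run.output, m=3, tau=91, T_steps=365,
...                  window_len=1095).fit()
>>> res.crossing_time  # doctest: +SKIP
23.0
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .config import AnalysisConfig
from .series import SpatioTemporalField, UniformSeries
from .tracking import (
    LABEL_CSD,
    LABEL_SEASONAL,
    EigenTrack,
    classify_tracks,
    detect_crossing,
    extract_spatial_mode,
    match_tracks,
    mode_change_map,
    rolling_floquet,
)

__all__ = ["FloquetDMD", "FloquetDMDResults"]


class FloquetDMD:
    """Rolling Floquet-multiplier stability model for one series or field.

    Parameters may be given as an :class:`AnalysisConfig` or as keyword
    overrides of its fields (``m``, ``tau``, ``T_steps``, ``window_len``,
    ``stride``, ``center``, ``rank``, thresholds, ...). ``center`` defaults to
    off for scalar series and on for spatial fields.
    """

    def __init__(
        self,
        data: UniformSeries | SpatioTemporalField,
        config: AnalysisConfig | None = None,
        **overrides,
    ) -> None:
        if not isinstance(data, (UniformSeries, SpatioTemporalField)):
            raise TypeError("data must be a UniformSeries or SpatioTemporalField")
        if config is None:
            if "center" not in overrides:
                overrides["center"] = isinstance(data, SpatioTemporalField)
            config = AnalysisConfig(**overrides)
        elif overrides:
            d = config.to_dict()
            d.update(overrides)
            config = AnalysisConfig.from_dict(d)
        self.data = data
        self.config = config

    @classmethod
    def from_dataframe(cls, df, time_col: str = "time", value_col: str = "value",
                       **kwargs) -> "FloquetDMD":
        """Build from a DataFrame with time and value columns."""
        series = UniformSeries(df[time_col].to_numpy(float),
                               df[value_col].to_numpy(float))
        return cls(series, **kwargs)

    def fit(self) -> "FloquetDMDResults":
        c = self.config
        track = rolling_floquet(
            self.data,
            c.embedding,
            rank=c.rank,
            max_rank=c.max_rank,
            max_missing_frac=c.max_missing_frac,
        )
        if track.n_windows >= 2:
            match_tracks(track, max_jump=c.max_jump, method=c.match_method)
            classify_tracks(
                track,
                seasonal_band=c.seasonal_band,
                min_coverage=c.min_coverage,
                noise_floor=c.noise_floor,
            )
            detect_crossing(track, threshold=c.threshold, persistence=c.persistence)
        return FloquetDMDResults(self, track)


class FloquetDMDResults:
    """Fitted eigenvalue tracks, labels and the detected crossing (if any)."""

    def __init__(self, model: FloquetDMD, track: EigenTrack) -> None:
        self.model = model
        self.track = track

    # -- estimates ---------------------------------------------------------
    @property
    def window_times(self) -> np.ndarray:
        return self.track.window_times

    @property
    def filtered_max(self) -> np.ndarray:
        """Per-window maximum |rho| over non-seasonal eigenvalues."""
        return self.track.filtered_max

    @property
    def crossing_time(self) -> float | None:
        return self.track.crossing_time

    @property
    def labels(self) -> list[str]:
        return self.track.labels

    def track_magnitudes(self, label: str) -> tuple[np.ndarray, np.ndarray]:
        """(times, |rho|) of the first track carrying ``label``."""
        if label not in self.track.labels:
            raise ValueError(f"no track labelled {label!r}")
        return self.track.track_magnitudes(self.track.labels.index(label))

    def seasonal_magnitudes(self) -> tuple[np.ndarray, np.ndarray]:
        return self.track_magnitudes(LABEL_SEASONAL)

    def candidate_magnitudes(self) -> tuple[np.ndarray, np.ndarray]:
        return self.track_magnitudes(LABEL_CSD)

    # -- spatial diagnostics ----------------------------------------------
    def spatial_mode(self, window: int, which: int = 0):
        """Unit-norm magnitude map of one mode's first spatial component."""
        return extract_spatial_mode(self.track.fits[window], self.track.n_space, which)

    def mode_change(self, early_windows, late_windows) -> np.ndarray:
        """Median candidate-mode map over late windows minus early windows."""
        return mode_change_map(self.track, early_windows, late_windows)

    # -- presentation ------------------------------------------------------
    def summary(self) -> str:
        t = self.track
        lines = [
            "Floquet-multiplier stability analysis",
            "=" * 45,
            f"windows analysed      : {t.n_windows}  (skipped: {len(t.skipped)})",
            f"window span (samples) : {self.model.config.embedding.span}",
            f"embedding (m, tau, T) : ({self.model.config.m}, "
            f"{self.model.config.tau}, {self.model.config.T_steps})",
            f"mean rank used        : {np.mean([f.rank_used for f in t.fits]):.2f}",
        ]
        counts = {}
        for lab in t.labels:
            counts[lab] = counts.get(lab, 0) + 1
        lines.append(f"track labels          : {counts}")
        if t.filtered_max is not None:
            lines.append(
                f"filtered max |rho|    : first {t.filtered_max[0]:.4f}"
                f" -> last {t.filtered_max[-1]:.4f}"
            )
        if LABEL_SEASONAL in t.labels:
            _, mag = self.seasonal_magnitudes()
            lines.append(
                f"seasonal track |rho|  : {mag.min():.4f} .. {mag.max():.4f}"
            )
        cross = "none detected" if t.crossing_time is None else f"t = {t.crossing_time:g}"
        lines.append(f"threshold crossing    : {cross}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Eigenvalue magnitudes through time, coloured by track label."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        colors = {LABEL_SEASONAL: "tab:red", LABEL_CSD: "tab:blue"}
        for k, chain in enumerate(self.track.tracks):
            t, mag = self.track.track_magnitudes(k)
            lab = self.track.labels[k] if self.track.labels else None
            ax.plot(t, mag, color=colors.get(lab, "0.8"),
                    lw=1.5 if lab in colors else 0.6,
                    label=lab if lab in colors else None)
        ax.axhline(1.0, color="k", ls="--", lw=0.8)
        if self.crossing_time is not None:
            ax.axvline(self.crossing_time, color="k", lw=0.8)
        ax.set_xlabel("time")
        ax.set_ylabel(r"$|\rho|$")
        handles, labels_ = ax.get_legend_handles_labels()
        uniq = dict(zip(labels_, handles))
        if uniq:
            ax.legend(uniq.values(), uniq.keys(), frameon=False)
        return ax

    def save(self, out_dir: str | Path, prefix: str = "floquet") -> None:
        """Write the eigentrack CSV, summary JSON and config echo."""
        from .io import write_config_yaml, write_eigentrack_csv, write_summary_json

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_eigentrack_csv(self.track, out / f"{prefix}_eigentrack.csv")
        write_summary_json(self.track, out / f"{prefix}_summary.json")
        write_config_yaml(self.model.config.to_dict(), out / f"{prefix}_config.yaml")
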