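"""Scalar ECM-accumulation endpoints.

Fixed-threshold total stain intensity, viability normalisation (stain
signal per PrestoBlue unit), radioactive-count normalisation (ECM cpm per
cell cpm), percent inhibition against plate controls, fold change, and
relative qPCR expression by the ddCt method against the geometric mean of
the housekeepers B2M, HMBS and TBP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AssayWindowError, ParameterError
from .io_imaging import PlateLayout, WellImage

DEFAULT_HOUSEKEEPERS = ("B2M", "HMBS", "TBP")


def total_intensity_above_threshold(image: WellImage | np.ndarray, threshold: float) -> float:
    """Sum of intensities of pixels strictly above the fixed threshold.

    The strict inequality is a stated convention: a flat image at exactly
    the threshold contributes nothing.
    """
    if threshold < 0:
        raise ParameterError(f"threshold must be >= 0, got {threshold}")
    px = image.pixels if isinstance(image, WellImage) else np.asarray(image)
    sel = px > threshold
    return float(px[sel].astype(np.float64).sum())


def mean_intensity_above_threshold(image: WellImage | np.ndarray, threshold: float) -> float:
    """Mean intensity of pixels strictly above the threshold (0 if none pass)."""
    if threshold < 0:
        raise ParameterError(f"threshold must be >= 0, got {threshold}")
    px = image.pixels if isinstance(image, WellImage) else np.asarray(image)
    sel = px > threshold
    return float(px[sel].astype(np.float64).mean()) if sel.any() else 0.0


def estimate_fixed_threshold(images: list[WellImage | np.ndarray], n_sigma: float = 3.0) -> float:
    """Estimate the plate's fixed threshold from unstimulated-control wells.

    Threshold = background mode (histogram peak of the pooled integer
    counts) + ``n_sigma`` robust sigmas (1.4826 x MAD). On control wells the
    vast majority of pixels are background, so the mode and MAD characterise
    the background distribution.
    """
    if not images:
        raise ParameterError("at least one control image required to estimate a threshold")
    pooled = np.concatenate([
        (im.pixels if isinstance(im, WellImage) else np.asarray(im)).ravel() for im in images
    ])
    counts = np.bincount(pooled.astype(np.int64))
    mode = int(np.argmax(counts))
    sigma = 1.4826 * float(np.median(np.abs(pooled.astype(np.float64) - np.median(pooled))))
    return mode + n_sigma * sigma


def normalize_to_viability(ecm: float, viability: float) -> float:
    """ECM stain signal per unit viability signal (cell-number correction)."""
    if viability <= 0:
        raise ParameterError(f"viability signal must be > 0 (dead/empty well?), got {viability}")
    return ecm / viability


def normalize_radioactive(ecm_cpm: float, cell_cpm: float) -> float:
    """ECM radioactivity per unit cellular radioactivity."""
    if cell_cpm <= 0:
        raise ParameterError(f"cell cpm must be > 0, got {cell_cpm}")
    if ecm_cpm < 0:
        raise ParameterError(f"ecm cpm must be >= 0, got {ecm_cpm}")
    return ecm_cpm / cell_cpm


def percent_inhibition(value: float, stim_control_mean: float, unstim_control_mean: float) -> float:
    """Percent inhibition anchored at the plate controls.

    0% at the stimulated-control mean, 100% at the unstimulated-control
    mean; values outside the window extrapolate linearly.
    """
    window = stim_control_mean - unstim_control_mean
    if window == 0:
        raise AssayWindowError("stimulated and unstimulated control means are equal: no assay window")
    return 100.0 * (stim_control_mean - value) / window


def fold_change(treated: float, control: float) -> float:
    if control <= 0:
        raise ParameterError(f"control value must be > 0, got {control}")
    return treated / control


@dataclass(frozen=True)
class CtRecord:
    """qPCR record: target Ct plus housekeeper Cts (cycles)."""

    sample_id: str
    target_ct: float
    housekeeper_cts: dict[str, float] = field(default_factory=dict)

    def reference_ct(self, housekeepers: tuple[str, ...] = DEFAULT_HOUSEKEEPERS) -> float:
        """Arithmetic mean of the housekeeper Cts.

        Since expression is 2^-Ct, averaging Cts equals normalising to the
        geometric mean of the housekeepers on the linear scale.
        """
        missing = [g for g in housekeepers if g not in self.housekeeper_cts]
        if missing:
            raise ParameterError(f"sample {self.sample_id!r} is missing housekeeper Ct(s): {missing}")
        cts = [self.housekeeper_cts[g] for g in housekeepers]
        if not all(np.isfinite(cts)) or any(c <= 0 for c in cts):
            raise ParameterError(f"sample {self.sample_id!r} has non-finite or non-positive housekeeper Cts")
        return float(np.mean(cts))


def delta_delta_ct(
    sample: CtRecord, calibrator: CtRecord, housekeepers: tuple[str, ...] = DEFAULT_HOUSEKEEPERS
) -> float:
    """Relative expression of sample vs calibrator: 2^-(dCt_sample - dCt_calibrator)."""
    d_sample = sample.target_ct - sample.reference_ct(housekeepers)
    d_cal = calibrator.target_ct - calibrator.reference_ct(housekeepers)
    return float(2.0 ** -(d_sample - d_cal))


def quantify_plate(layout: PlateLayout, measurements: pd.DataFrame) -> pd.DataFrame:
    """Join per-well measurements onto the plate layout and normalise.

    ``measurements`` needs columns well_id, ecm_intensity, viability_signal.
    Adds normalized_ecm = ecm / viability, and, when both control roles are
    present, percent_inhibition anchored on the mean normalised signal of
    the stimulated / unstimulated control wells.
    """
    df = layout.table.merge(measurements, on="well_id", how="inner", validate="one_to_one")
    df["normalized_ecm"] = [
        normalize_to_viability(e, v) for e, v in zip(df["ecm_intensity"], df["viability_signal"])
    ]
    stim = df.loc[df["role"] == "stimulated-control", "normalized_ecm"]
    unstim = df.loc[df["role"] == "unstimulated-control", "normalized_ecm"]
    if len(stim) and len(unstim):
        s_mean, u_mean = float(stim.mean()), float(unstim.mean())
        df["percent_inhibition"] = [percent_inhibition(v, s_mean, u_mean) for v in df["normalized_ecm"]]
    return df
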