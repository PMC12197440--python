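"""Bundled reference tables from a published smartphone-TLC validation of
metformin tablet quality.

All tables are shipped as plain CSV and loaded into pandas DataFrames.  They
serve as numeric fixtures: repeatability summaries of retention-factor (Rf)
measurements, spiked-recovery results, published calibration-line parameters,
and a 16-sample market survey comparing four quantification methods
(smartphone densitometry, ImageJ densitometry, UV-Vis spectrophotometry and
HPLC) on 500 mg metformin tablets.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_rf_cv", "load_recovery", "load_sample_survey",
    "load_rf_repeatability", "load_conc_repeatability",
    "load_published_calibration",
]

CONTENT_COLUMNS = ["content_tlc_analyzer", "content_imagej",
                   "content_uv_vis", "content_hplc"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("tlcdens.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_rf_cv() -> pd.DataFrame:
    """Per-concentration CV (%) of replicate Rf measurements, by method."""
    return _read("rf_cv.csv")


def load_recovery() -> pd.DataFrame:
    """Spiked-recovery summaries (mean +/- sd, mg/mL and %), by method."""
    return _read("recovery.csv")


def load_sample_survey() -> pd.DataFrame:
    """16 market-sampled metformin tablets: Rf and API content (mg/tablet)
    by four methods.  Label claim 500 mg; pharmacopeial band 450-550 mg."""
    return _read("sample_survey.csv")


def load_rf_repeatability() -> pd.DataFrame:
    """Overall Rf repeatability (mean, sd, n) for each densitometry method."""
    return _read("rf_repeatability.csv")


def load_conc_repeatability() -> pd.DataFrame:
    """Replicate concentration measurements at 4/2/1 mg/mL, by method."""
    return _read("conc_repeatability.csv")


def load_published_calibration() -> pd.DataFrame:
    """Published straight-line calibration parameters (AUC vs mg/mL)."""
    return _read("published_calibration.csv")
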