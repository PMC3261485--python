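"""Published reference values for DTI indices in the healthy adult spinal cord.

These are literature cluster-centroid values (mean +/- SD over nine healthy
subjects) for white matter, grey matter and CSF in the cervical, thoracic and
lumbar cord, together with the grey-matter cross-sectional area fractions of
each region from anatomical studies.  They serve two purposes: as defaults for
the synthetic phantom's tissue parameters, and as reference points when
checking that the analysis pipeline reproduces plausible healthy-cord values.

MD is expressed in 1e-3 mm^2/s throughout; FA is dimensionless.
"""

from __future__ import annotations

import pandas as pd

#: Grey-matter fraction of the cord's transverse cross-sectional area, percent.
GM_AREA_PERCENT: dict[str, float] = {
    "cervical": 18.0,
    "thoracic": 13.2,
    "lumbar": 36.3,
}

#: Region order used for display and regression.
REGIONS: tuple[str, ...] = ("cervical", "thoracic", "lumbar")

#: Tissue order: white matter, grey matter, cerebrospinal fluid.
TISSUES: tuple[str, ...] = ("WM", "GM", "CSF")

_ROWS = [
    # region, tissue, md_mean, md_sd, fa_mean, fa_sd
    ("cervical", "WM", 0.97, 0.32, 0.70, 0.08),
    ("cervical", "GM", 1.80, 0.61, 0.45, 0.07),
    ("cervical", "CSF", 3.06, 1.02, 0.28, 0.08),
    ("thoracic", "WM", 0.96, 0.32, 0.71, 0.08),
    ("thoracic", "GM", 1.90, 0.34, 0.44, 0.08),
    ("thoracic", "CSF", 3.12, 0.61, 0.27, 0.07),
    ("lumbar", "WM", 0.87, 0.32, 0.65, 0.08),
    ("lumbar", "GM", 1.70, 0.34, 0.44, 0.08),
    ("lumbar", "CSF", 2.72, 0.33, 0.30, 0.07),
]


def regional_reference() -> pd.DataFrame:
    """Reference per-region, per-tissue centroid table.

    Returns a DataFrame with columns ``region, tissue, md_mean, md_sd,
    fa_mean, fa_sd`` (MD in 1e-3 mm^2/s).
    """
    return pd.DataFrame(
        _ROWS, columns=["region", "tissue", "md_mean", "md_sd", "fa_mean", "fa_sd"]
    )


def regional_wm_fa() -> dict[str, float]:
    """White-matter FA centroid per region, in REGIONS order."""
    df = regional_reference()
    wm = df[df.tissue == "WM"].set_index("region")["fa_mean"]
    return {r: float(wm[r]) for r in REGIONS}
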