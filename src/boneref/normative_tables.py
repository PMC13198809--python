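"""Published normative descriptive statistics for multi-stack HRpQCT.

Sex- and site-specific descriptive statistics (mean, SD, coefficient of
variation, short-term precision error PE_st, median relative change per
annum, and short-term trend assessment interval TAI_st) for the reference
cohort of 381 healthy adults (144 F, 237 M, 20-92 yr) scanned with the
double-stack radius / triple-stack tibia protocol on second-generation
HRpQCT.  These values parameterize the synthetic cohort generator and act
as published anchors for consistency checks.

Values are stored exactly as printed (2-3 decimals); helper functions
expose the number of printed decimals so that consistency checks can
account for input rounding.
"""

from __future__ import annotations

import io
from functools import lru_cache

import pandas as pd

__all__ = [
    "descriptive_statistics",
    "get_row",
    "printed_decimals",
    "SIX_PARAMETERS",
]

#: The six size-independent parameters selected for bone-health profiling,
#: in fixed radar-spoke order.
SIX_PARAMETERS: tuple[str, ...] = (
    "Tot.vBMD",
    "Ct.vBMD",
    "Rel.Ct.Th",
    "Tb.BV/TV",
    "Tb.DA",
    "app_sigma_y",
)

# sex,site,parameter,mu,sigma,cv,pe_st (%),annual_change (%/yr),tai_st (yr)
# FN_aBMD is a DXA femoral-neck measurement without a radius/tibia site;
# it is keyed under site "fn".
_TABLE_CSV = """\
sex,site,parameter,mu,sigma,cv,pe_st,annual_change,tai_st
F,fn,FN_aBMD,0.849,0.121,0.143,1.200,-0.603,3.582
F,tibia,Tot.vBMD,0.266,0.036,0.135,0.427,-0.753,1.021
F,tibia,Ct.vBMD,0.865,0.032,0.037,0.37,-0.657,1.013
F,tibia,Tb.BV/TV,0.286,0.044,0.153,0.654,-0.367,3.207
F,tibia,Rel.Ct.Th,0.065,0.012,0.179,1.315,-1.024,2.312
F,tibia,app_sigma_y,10.988,2.279,0.207,3.514,-1.368,4.625
F,tibia,Tb.DA,1.726,0.071,0.041,1.582,-0.192,14.822
F,tibia,F_y,9.967,2.187,0.219,4.13,-0.872,8.521
F,tibia,Ct.Th,1.096,0.159,0.145,1.388,-0.874,2.86
F,tibia,Ct.Po,0.015,0.006,0.427,5.176,1.142,8.158
F,tibia,Tb.N,1.59,0.155,0.098,2.027,0.197,18.518
F,tibia,Tb.Sp,0.591,0.069,0.116,1.561,-0.078,36.215
F,tibia,Tb.Th,0.251,0.018,0.073,0.605,-0.036,30.175
F,tibia,Tb.vBMD,0.197,0.031,0.158,0.509,-0.41,2.235
F,radius,Tot.vBMD,0.297,0.048,0.162,0.591,-1.178,0.903
F,radius,Ct.vBMD,0.926,0.04,0.043,1.247,-0.414,5.424
F,radius,Tb.BV/TV,0.209,0.045,0.215,3.7,-0.479,13.916
F,radius,Rel.Ct.Th,0.113,0.021,0.19,3.21,-0.91,6.347
F,radius,app_sigma_y,13.656,3.959,0.29,5.71,-1.32,7.788
F,radius,Tb.DA,1.822,0.103,0.056,1.567,-0.046,61.731
F,radius,F_y,3.809,0.947,0.249,4.62,-1.718,4.841
F,radius,Ct.Th,1.057,0.154,0.146,1.843,-0.785,4.227
F,radius,Ct.Po,0.003,0.002,0.621,11.262,3.047,6.654
F,radius,Tb.N,0.145,0.031,0.213,3.314,-0.573,10.406
F,radius,Tb.Sp,1.456,0.177,0.121,2.799,-0.533,9.46
F,radius,Tb.Th,0.655,0.094,0.143,2.866,0.576,8.958
F,radius,Tb.vBMD,0.215,0.012,0.054,1.96,-0.001,2468.193
M,fn,FN_aBMD,0.95,0.164,0.173,1.200,-0.418,5.163
M,tibia,Tot.vBMD,0.3,0.047,0.157,0.427,-0.591,1.301
M,tibia,Ct.vBMD,0.813,0.038,0.047,0.37,-0.591,1.126
M,tibia,Tb.BV/TV,0.347,0.05,0.143,0.654,-0.299,3.937
M,tibia,Rel.Ct.Th,0.07,0.021,0.296,1.315,-1.44,1.644
M,tibia,app_sigma_y,12.956,3.184,0.246,3.514,-1.408,4.493
M,tibia,Tb.DA,1.687,0.083,0.049,1.582,-0.066,43.424
M,tibia,F_y,14.775,3.657,0.247,4.13,-1.055,7.045
M,tibia,Ct.Th,1.314,0.323,0.246,1.388,-1.274,1.96
M,tibia,Ct.Po,0.028,0.01,0.379,5.176,0.393,23.703
M,tibia,Tb.N,1.704,0.177,0.104,2.027,-0.067,54.715
M,tibia,Tb.Sp,0.545,0.068,0.124,1.561,0.318,8.843
M,tibia,Tb.Th,0.275,0.024,0.089,0.605,-0.047,23.165
M,tibia,Tb.vBMD,0.238,0.036,0.151,0.509,-0.342,2.676
M,radius,Tot.vBMD,0.335,0.051,0.153,0.591,-0.585,1.82
M,radius,Ct.vBMD,0.887,0.035,0.04,1.247,-0.229,9.798
M,radius,Tb.BV/TV,0.291,0.05,0.172,3.7,-0.487,13.68
M,radius,Rel.Ct.Th,0.115,0.025,0.214,3.21,-0.62,9.32
M,radius,app_sigma_y,16.424,4.285,0.261,5.71,-1.126,9.128
M,radius,Tb.DA,1.803,0.108,0.06,1.567,-0.087,32.587
M,radius,F_y,6.015,1.669,0.277,4.62,-0.328,25.375
M,radius,Ct.Th,1.226,0.207,0.169,1.843,-0.588,5.643
M,radius,Ct.Po,0.007,0.006,0.776,11.262,2.367,8.564
M,radius,Tb.N,0.199,0.034,0.17,3.314,-0.548,10.885
M,radius,Tb.Sp,1.583,0.234,0.148,2.799,-0.442,11.394
M,radius,Tb.Th,0.568,0.072,0.127,2.866,0.657,7.854
M,radius,Tb.vBMD,0.242,0.017,0.069,1.96,0.083,42.676
"""

_NUMERIC = ("mu", "sigma", "cv", "pe_st", "annual_change", "tai_st")


@lru_cache(maxsize=1)
def _raw() -> pd.DataFrame:
    return pd.read_csv(io.StringIO(_TABLE_CSV), dtype=str)


@lru_cache(maxsize=1)
def descriptive_statistics() -> pd.DataFrame:
    """The full descriptive-statistics table with numeric columns."""
    df = _raw().copy()
    for col in _NUMERIC:
        df[col] = df[col].astype(float)
    return df


def get_row(sex: str, site: str, parameter: str) -> pd.Series:
    """One table row, raising KeyError if absent."""
    df = descriptive_statistics()
    m = (df["sex"] == sex) & (df["site"] == site) & (df["parameter"] == parameter)
    sub = df[m]
    if len(sub) != 1:
        raise KeyError(f"no unique row for ({sex}, {site}, {parameter})")
    return sub.iloc[0]


def printed_decimals(sex: str, site: str, parameter: str, column: str) -> int:
    """Number of decimal places the value was published with."""
    df = _raw()
    m = (df["sex"] == sex) & (df["site"] == site) & (df["parameter"] == parameter)
    text = df[m].iloc[0][column]
    return len(text.split(".")[1]) if "." in text else 0
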