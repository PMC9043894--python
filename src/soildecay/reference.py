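"""Bundled reference estimates for the default 36-condition factorial design.

These constants are the package's built-in parameter set: per-condition
fitted models for the Gongzhuling soil (three temperatures x three water
contents), the sterilized / nonsterilized pair run at 35 degC and 50%
water content, and the published per-factor-level summary means used by
the factor-influence ranking.  They serve as simulation ground truth and
as regression baselines for the test suite.

Conditions are keyed by ``(temperature_C, water_content_pct)``.
"""

from __future__ import annotations

from .models import FirstOrderParams, PlateauParams

SITES = ("Gongzhuling", "Jinan", "Beijing", "Zhengzhou")
TEMPERATURES = (15.0, 25.0, 35.0)
WATER_CONTENTS = (20.0, 33.0, 50.0)

# First-order fits Y = a * exp(-b t), Gongzhuling soil.
FIRST_ORDER_GONGZHULING: dict[tuple[float, float], FirstOrderParams] = {
    (15.0, 20.0): FirstOrderParams(a=336.25, b=0.046),
    (15.0, 33.0): FirstOrderParams(a=346.22, b=0.0661),
    (15.0, 50.0): FirstOrderParams(a=319.48, b=0.0378),
    (25.0, 20.0): FirstOrderParams(a=370.36, b=0.1199),
    (25.0, 33.0): FirstOrderParams(a=351.53, b=0.1146),
    (25.0, 50.0): FirstOrderParams(a=310.77, b=0.0747),
    (35.0, 20.0): FirstOrderParams(a=375.38, b=0.1861),
    (35.0, 33.0): FirstOrderParams(a=372.06, b=0.201),
    (35.0, 50.0): FirstOrderParams(a=347.45, b=0.0742),
}

# Plateau fits Y = y0 + a * exp(-b t), Gongzhuling soil.
PLATEAU_GONGZHULING: dict[tuple[float, float], PlateauParams] = {
    (15.0, 20.0): PlateauParams(y0=83.58, a=266.69, b=0.0976),
    (15.0, 33.0): PlateauParams(y0=74.37, a=286.73, b=0.1291),
    (15.0, 50.0): PlateauParams(y0=87.33, a=246.25, b=0.0873),
    (25.0, 20.0): PlateauParams(y0=22.09, a=352.16, b=0.1399),
    (25.0, 33.0): PlateauParams(y0=44.53, a=319.43, b=0.1739),
    (25.0, 50.0): PlateauParams(y0=51.36, a=274.35, b=0.1369),
    (35.0, 20.0): PlateauParams(y0=15.92, a=362.61, b=0.2072),
    (35.0, 33.0): PlateauParams(y0=11.92, a=362.25, b=0.2168),
    (35.0, 50.0): PlateauParams(y0=4.58, a=343.26, b=0.0762),
}

# Reported goodness of fit (R^2) for the Gongzhuling conditions.
R2_FIRST_ORDER_GONGZHULING: dict[tuple[float, float], float] = {
    (15.0, 20.0): 0.9105,
    (15.0, 33.0): 0.9227,
    (15.0, 50.0): 0.8938,
    (25.0, 20.0): 0.9898,
    (25.0, 33.0): 0.9608,
    (25.0, 50.0): 0.9026,
    (35.0, 20.0): 0.9944,
    (35.0, 33.0): 0.9750,
    (35.0, 50.0): 0.9916,
}
R2_PLATEAU_GONGZHULING: dict[tuple[float, float], float] = {
    (15.0, 20.0): 0.9727,
    (15.0, 33.0): 0.9756,
    (15.0, 50.0): 0.9640,
    (25.0, 20.0): 0.9939,
    (25.0, 33.0): 0.9811,
    (25.0, 50.0): 0.9215,
    (35.0, 20.0): 0.9962,
    (35.0, 33.0): 0.9766,
    (35.0, 50.0): 0.9915,
}

# DT50 (days) as printed alongside the first-order fits, one decimal.
REPORTED_DT50_GONGZHULING: dict[tuple[float, float], float] = {
    (15.0, 20.0): 15.1,
    (15.0, 33.0): 10.5,
    (15.0, 50.0): 18.3,
    (25.0, 20.0): 5.8,
    (25.0, 33.0): 6.1,
    (25.0, 50.0): 9.3,
    (35.0, 20.0): 3.7,
    (35.0, 33.0): 3.5,
    (35.0, 50.0): 9.3,
}

# Sterilization pair (Gongzhuling soil, 35 degC, 50% water content).
FIRST_ORDER_STERILIZED = FirstOrderParams(a=346.34, b=0.059)
PLATEAU_STERILIZED = PlateauParams(y0=48.82, a=302.95, b=0.0827)
FIRST_ORDER_NONSTERILIZED = FirstOrderParams(a=347.45, b=0.0742)
PLATEAU_NONSTERILIZED = PlateauParams(y0=4.58, a=343.26, b=0.0762)
REPORTED_DT50_STERILIZED = 11.75  # two decimals as printed
REPORTED_DT50_NONSTERILIZED = 9.34
R2_STERILIZED = {"first_order": 0.9717, "plateau": 0.9935}
R2_NONSTERILIZED = {"first_order": 0.9916, "plateau": 0.9915}

# Published per-factor-level means of the early-stage metric (DT50, days).
MEAN_DT50_BY_TEMPERATURE = {15.0: 17.3, 25.0: 7.7, 35.0: 4.3}
MEAN_DT50_BY_WATER_CONTENT = {20.0: 9.6, 33.0: 7.4, 50.0: 12.4}
MEAN_DT50_BY_SITE = {
    "Gongzhuling": 9.1,
    "Jinan": 6.6,
    "Beijing": 10.1,
    "Zhengzhou": 13.3,
}

# Published per-factor-level means of the late-stage metric (y0, ng/g).
MEAN_Y0_BY_TEMPERATURE = {15.0: 85.7, 25.0: 34.2, 35.0: 15.5}
MEAN_Y0_BY_WATER_CONTENT = {20.0: 37.1, 33.0: 47.3, 50.0: 50.1}
MEAN_Y0_BY_SITE = {
    "Gongzhuling": 43.9,
    "Beijing": 38.6,
    "Jinan": 50.2,
    "Zhengzhou": 47.8,
}
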