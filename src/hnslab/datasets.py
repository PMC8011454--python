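"""Small reference summaries bundled for worked examples.

``UCN_OVEREXPRESSION_BANDPOWER`` holds group-mean spectral band powers
(mean ± SEM, mmHg²) from a radiotelemetry experiment in which urocortin was
over-expressed in the paraventricular nucleus of spontaneously hypertensive
rats, recorded before transfection (day 0) and 14 days after. The very-low
frequency (VLF) components of systolic and diastolic pressure variability
fell between the two time points; the day-14 minus day-0 differences of the
group means are the worked-example quantities reproduced by
:func:`band_power_change`.
"""

from __future__ import annotations

__all__ = ["UCN_OVEREXPRESSION_BANDPOWER", "band_power_change"]

#: Group means ± SEM of spectral band powers (mmHg²) at day 0 and day 14.
UCN_OVEREXPRESSION_BANDPOWER = {
    "total_sbp": {"d0": (7.08, 1.75), "d14": (4.2, 0.96)},
    "vlf_sbp": {"d0": (4.36, 0.65), "d14": (2.46, 0.65)},
    "vlf_dbp": {"d0": (3.52, 0.67), "d14": (1.86, 0.39)},
}


def band_power_change(component: str) -> float:
    """Day-14 minus day-0 difference of group-mean band power, mmHg².

    >>> band_power_change("vlf_sbp")
    -1.9
    """
    entry = UCN_OVEREXPRESSION_BANDPOWER[component]
    return round(entry["d14"][0] - entry["d0"][0], 10)
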