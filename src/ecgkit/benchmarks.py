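"""Published benchmark figures for ambulatory QRS detection.

Two reference tables accompany the toolkit.  ``MITDB_QRS_TABLE`` lists the
per-record QRS sensitivity and positive predictivity (in percent) reported
for the 48 MIT-BIH Arrhythmia Database records by the remote-monitoring
algorithm this toolkit re-implements, together with each record's total
beat count.  ``MODULE_TABLE_CNN`` / ``MODULE_TABLE_PT`` list, for twenty
functional modules, the Se / P+ / Acc / F1 figures reported for the
image-based CNN detector and the Pan-Tompkins comparator on a private
wearable-ECG dataset.

These numbers are inputs to consistency checks (the Acc and F-measure
identities, the column-mean conventions of :func:`ecgkit.evaluate.per_record_report`),
not outputs of this package.  Note: in rows 2, 10 and 16 of the module
tables the published F1 values are transposed between the two method
columns (each printed F1 reproduces the *other* method's Se/P+ to within
5e-4); ``F1_TRANSPOSED_ROWS`` records this so downstream checks can state
it explicitly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "MITDB_QRS_TABLE",
    "MODULE_TABLE_CNN",
    "MODULE_TABLE_PT",
    "F1_TRANSPOSED_ROWS",
    "mitdb_qrs_table",
    "module_table",
]

# record, total beats, QRS Se (%), QRS P+ (%)
MITDB_QRS_TABLE: list[tuple[str, int, float, float]] = [
    ("100", 2273, 99.78, 100.00),
    ("101", 1865, 99.89, 99.89),
    ("102", 2187, 98.63, 100.00),
    ("103", 2084, 99.62, 100.00),
    ("104", 2229, 97.76, 99.41),
    ("105", 2572, 99.92, 99.65),
    ("106", 2027, 95.56, 100.00),
    ("107", 2137, 99.58, 100.00),
    ("108", 1763, 99.43, 99.72),
    ("109", 2532, 99.64, 100.00),
    ("111", 2124, 99.72, 100.00),
    ("112", 2539, 99.80, 100.00),
    ("113", 1795, 99.78, 100.00),
    ("114", 1879, 99.73, 100.00),
    ("115", 1953, 99.80, 100.00),
    ("116", 2412, 98.92, 100.00),
    ("117", 1535, 99.80, 100.00),
    ("118", 2278, 99.87, 100.00),
    ("119", 1987, 90.59, 100.00),
    ("121", 1863, 99.73, 100.00),
    ("122", 2476, 99.80, 100.00),
    ("123", 1518, 99.60, 100.00),
    ("124", 1619, 98.95, 100.00),
    ("200", 2601, 99.58, 100.00),
    ("201", 1963, 95.67, 100.00),
    ("202", 2136, 98.92, 100.00),
    ("203", 2980, 96.31, 100.00),
    ("205", 2656, 99.62, 100.00),
    ("207", 2332, 87.61, 100.00),
    ("208", 2955, 75.84, 100.00),
    ("209", 3005, 99.83, 100.00),
    ("210", 2650, 97.09, 100.00),
    ("212", 2748, 99.82, 100.00),
    ("213", 3251, 98.83, 100.00),
    ("214", 2262, 99.69, 100.00),
    ("215", 3363, 99.58, 100.00),
    ("217", 2208, 99.46, 100.00),
    ("219", 2154, 99.49, 100.00),
    ("220", 2048, 99.76, 100.00),
    ("221", 2427, 96.79, 100.00),
    ("222", 2483, 98.23, 100.00),
    ("223", 2605, 94.89, 100.00),
    ("228", 2053, 95.91, 100.00),
    ("230", 2256, 99.78, 100.00),
    ("231", 1571, 99.81, 100.00),
    ("232", 1780, 99.89, 99.94),
    ("233", 3079, 99.32, 100.00),
    ("234", 2753, 99.71, 100.00),
]

#: Published column means of MITDB_QRS_TABLE (percent).
MITDB_AVERAGE_SE = 98.07
MITDB_AVERAGE_PPV = 99.97

# 20 functional-module rows: (Se, PPV, Acc, F1)
MODULE_TABLE_CNN: list[tuple[float, float, float, float]] = [
    (0.9953, 0.9908, 0.9863, 0.9931),
    (0.9716, 0.9941, 0.9660, 0.9845),
    (0.9752, 0.9857, 0.9616, 0.9804),
    (0.9953, 0.9995, 0.9948, 0.9974),
    (0.9860, 0.9754, 0.9621, 0.9807),
    (0.9645, 0.9828, 0.9484, 0.9735),
    (0.9919, 0.9860, 0.9781, 0.9889),
    (0.9881, 0.9851, 0.9736, 0.9866),
    (0.9827, 0.9596, 0.9437, 0.9710),
    (0.9592, 0.9929, 0.9526, 0.9895),
    (0.9939, 0.9747, 0.9688, 0.9842),
    (0.9978, 0.9974, 0.9952, 0.9976),
    (0.9910, 0.9959, 0.9869, 0.9934),
    (0.9830, 0.9862, 0.9697, 0.9846),
    (0.9796, 0.9572, 0.9384, 0.9682),
    (0.9402, 0.9461, 0.8924, 0.9740),
    (0.9844, 0.9818, 0.9668, 0.9831),
    (0.9489, 0.9644, 0.9168, 0.9566),
    (0.9815, 0.9923, 0.9740, 0.9869),
    (0.9811, 0.9907, 0.9721, 0.9858),
]

MODULE_TABLE_PT: list[tuple[float, float, float, float]] = [
    (0.9958, 0.9922, 0.9881, 0.9940),
    (0.9857, 0.9834, 0.9695, 0.9827),
    (0.9079, 0.9128, 0.8354, 0.9103),
    (0.9995, 0.9991, 0.9986, 0.9993),
    (0.9808, 0.9586, 0.9410, 0.9696),
    (0.9774, 0.9738, 0.9524, 0.9756),
    (0.9953, 0.9790, 0.9745, 0.9871),
    (0.9902, 0.9868, 0.9772, 0.9885),
    (0.9637, 0.9529, 0.9199, 0.9583),
    (0.9865, 0.9924, 0.9791, 0.9757),
    (0.9898, 0.9099, 0.9015, 0.9482),
    (0.9958, 0.9908, 0.9866, 0.9933),
    (0.9943, 0.9762, 0.9708, 0.9852),
    (0.9898, 0.9728, 0.9631, 0.9812),
    (0.9850, 0.9806, 0.9662, 0.9828),
    (0.9749, 0.9731, 0.9493, 0.9432),
    (0.9757, 0.9636, 0.9410, 0.9696),
    (0.9758, 0.9634, 0.9409, 0.9696),
    (0.9834, 0.9814, 0.9654, 0.9824),
    (0.9814, 0.9816, 0.9637, 0.9815),
]

#: Published AVR rows (Se, PPV, Acc, F1) of the module tables.
MODULE_AVR_CNN = (0.9796, 0.9819, 0.9624, 0.9807)
MODULE_AVR_PT = (0.9814, 0.9710, 0.9542, 0.9762)

#: 1-based module rows whose printed F1 values are swapped between the
#: CNN and Pan-Tompkins columns in the published table.
F1_TRANSPOSED_ROWS = (2, 10, 16)


def mitdb_qrs_table() -> pd.DataFrame:
    """The per-record benchmark table as a DataFrame."""
    return pd.DataFrame(
        MITDB_QRS_TABLE, columns=["record", "total_beats", "se_pct", "ppv_pct"]
    )


def module_table(method: str) -> pd.DataFrame:
    """The 20-row functional-module table for 'cnn' or 'pt'."""
    tables = {"cnn": MODULE_TABLE_CNN, "pt": MODULE_TABLE_PT}
    if method not in tables:
        raise ValueError("method must be 'cnn' or 'pt'")
    df = pd.DataFrame(tables[method], columns=["se", "ppv", "acc", "f1"])
    df.index = np.arange(1, len(df) + 1)
    return df
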