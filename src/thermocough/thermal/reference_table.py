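"""Bundled reference validation measurements for the thermopile method.

Twenty-five bench measurements taken with the nine-zone validation plate:
the temperature reported by the calibrated thermopile (``measured_C``), the
plate thermometer's reading (``validation_C``) and the printed absolute
error (``error_C``), all in degrees Celsius.  The table is used as an input
for internal-consistency checks (``error == |measured - validation|`` up to
print rounding) and to anchor the validation-campaign output format.
"""

from __future__ import annotations

import pandas as pd

_ROWS: list[tuple[float, float, float]] = [
    (38.13, 38.5, 0.37),
    (38.477, 38.56, 0.083),
    (38.477, 38.5, 0.023),
    (38.5, 39.25, 0.75),
    (38.5, 39.25, 0.75),
    (37.37, 37.81, 0.44),
    (37.37, 37.81, 0.44),
    (37.89, 37.75, 0.14),
    (38.44, 37.81, 0.63),
    (37.72, 37.38, 0.34),
    (36.79, 37.38, 0.59),
    (37.88, 37.44, 0.44),
    (37.62, 37.44, 0.18),
    (37.58, 36.94, 0.64),
    (37.61, 36.88, 0.73),
    (37.06, 36.94, 0.12),
    (37.08, 36.94, 0.14),
    (37.06, 36.75, 0.31),
    (36.62, 36.69, 0.07),
    (37.08, 36.75, 0.33),
    (37.59, 36.69, 0.9),
    (36.44, 36.83, 0.39),
    (36.44, 36.69, 0.25),
    (36.5, 36.65, 0.15),
    (36.5, 36.75, 0.25),
]


def reference_validation_table() -> pd.DataFrame:
    """The bundled bench table as a DataFrame.

    Columns: ``measured_C``, ``validation_C``, ``error_C``.
    """
    return pd.DataFrame(_ROWS, columns=["measured_C", "validation_C", "error_C"])
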