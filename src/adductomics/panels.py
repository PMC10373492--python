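"""Reference panel of putative 2'-deoxyribonucleoside adducts.

Eleven adducts recurrently found to discriminate amphipods from contaminated
versus reference Baltic sediment sites, with their observed precursor
([M+H]+) and product ([(M - dR) + H]+) m/z, retention times, and — where a
single formula was assignable — the proposed neutral elemental composition.
Used as ground-truth plants for the simulator and as mass-accuracy anchors
in the tests.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["reference_panel"]

_PANEL = [
    # id, precursor m/z, product m/z, RT (min), neutral formula, C-vs-R direction
    ("H483", 529.2973, 413.2512, 10.6, "C22H44O12N2", "down"),
    ("H187", 406.2178, 290.1712, 11.5, "C17H31O8N3", "down"),
    ("L114", 258.0947, 142.0477, 3.30, None, "up"),
    ("L127", 266.0822, 150.0357, 8.20, None, "up"),
    ("H342", 459.2450, 343.1968, 10.3, "C20H34O8N4", "down"),
    ("L129", 266.1242, 150.0776, 9.90, None, "up"),
    ("H403", 482.2248, 366.1769, 4.50, "C21H31O8N5", "down"),
    ("H368", 466.2640, 350.2189, 14.0, "C20H33O5N8", "down"),
    ("L189", 291.0887, 175.0419, 7.80, None, "up"),
    ("H264", 430.1841, 314.1348, 10.2, None, "up"),
    ("H204", 411.2129, 295.1653, 17.1, None, "down"),
]


def reference_panel() -> pd.DataFrame:
    """The discriminating-adduct panel as a DataFrame indexed by adduct id."""
    df = pd.DataFrame(
        _PANEL,
        columns=["adduct_id", "precursor_mz", "product_mz", "rt", "formula", "direction"],
    )
    return df.set_index("adduct_id")
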