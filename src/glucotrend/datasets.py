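"""Published national reference numbers bundled for arithmetic validation.

Norway's national prescription registry (NorPD) publishes incident-user
counts of blood glucose-lowering drugs with person-year denominators and
rates per 100,000 person-years for 2006-2011.  The printed counts and
denominators are inputs here: recomputing each rate and Wald interval
from them exercises :func:`glucotrend.rates.incidence_rate` against an
independent published computation.  Insulins-only cells for 2011 are
absent in the source (the 12-month lookforward extends past registry
coverage), mirroring the observability logic of this package.

``ci_reproducible`` marks rows where the printed rate and both CI bounds
match round-half-away-from-zero of the Wald recomputation; the remaining
rows are printed with mixed rounding/truncation in the source and are
checked to within one unit only.
"""

from __future__ import annotations

import pandas as pd

_COLUMNS = [
    "stratum", "year", "outcome", "count", "person_years", "rate", "ci_low", "ci_high",
]

# stratum, year, outcome, incident count, person-years, printed rate, CI
_ROWS = [
    ("women", 2006, "any", 7531, 2347036, 320, 314, 328),
    ("women", 2007, "any", 7769, 2366461, 328, 321, 336),
    ("women", 2008, "any", 7677, 2390716, 321, 314, 328),
    ("women", 2009, "any", 7832, 2418595, 323, 317, 331),
    ("women", 2010, "any", 7778, 2445249, 318, 311, 325),
    ("women", 2011, "any", 7269, 2473228, 293, 287, 301),
    ("women", 2006, "oad", 6752, 2347036, 288, 281, 295),
    ("women", 2007, "oad", 6927, 2366461, 293, 286, 300),
    ("women", 2008, "oad", 6717, 2390716, 281, 274, 288),
    ("women", 2009, "oad", 6912, 2418595, 286, 279, 293),
    ("women", 2010, "oad", 6817, 2445249, 279, 272, 286),
    ("women", 2011, "oad", 6369, 2473228, 258, 251, 264),
    ("women", 2006, "insulin_only", 670, 2347036, 29, 26, 31),
    ("women", 2007, "insulin_only", 679, 2366461, 29, 27, 31),
    ("women", 2008, "insulin_only", 783, 2390716, 33, 31, 35),
    ("women", 2009, "insulin_only", 745, 2418595, 31, 29, 33),
    ("women", 2010, "insulin_only", 784, 2445249, 32, 30, 34),
    ("men", 2006, "any", 7829, 2314006, 338, 331, 346),
    ("men", 2007, "any", 8374, 2342823, 357, 350, 365),
    ("men", 2008, "any", 8655, 2377361, 364, 356, 372),
    ("men", 2009, "any", 8620, 2411205, 357, 350, 365),
    ("men", 2010, "any", 8605, 2443697, 352, 345, 360),
    ("men", 2011, "any", 8246, 2479989, 332, 325, 340),
    ("men", 2006, "oad", 6830, 2314006, 295, 288, 302),
    ("men", 2007, "oad", 7326, 2342823, 313, 306, 320),
    ("men", 2008, "oad", 7498, 2377361, 315, 308, 323),
    ("men", 2009, "oad", 7453, 2411205, 309, 302, 316),
    ("men", 2010, "oad", 7475, 2443697, 306, 299, 313),
    ("men", 2011, "oad", 7131, 2479989, 288, 281, 294),
    ("men", 2006, "insulin_only", 756, 2314006, 33, 30, 35),
    ("men", 2007, "insulin_only", 793, 2342823, 34, 32, 36),
    ("men", 2008, "insulin_only", 845, 2377361, 36, 33, 38),
    ("men", 2009, "insulin_only", 839, 2411205, 35, 33, 37),
    ("men", 2010, "insulin_only", 813, 2443697, 33, 31, 36),
    ("total", 2006, "any", 15360, 4661041, 329, 324, 334),
    ("total", 2007, "any", 16143, 4709284, 342, 338, 348),
    ("total", 2008, "any", 16332, 4768077, 342, 337, 348),
    ("total", 2009, "any", 16452, 4829800, 340, 335, 346),
    ("total", 2010, "any", 16383, 4888946, 335, 330, 340),
    ("total", 2011, "any", 15515, 4953217, 313, 308, 318),
    ("total", 2006, "oad", 13582, 4661041, 291, 287, 297),
    ("total", 2007, "oad", 14253, 4709284, 303, 298, 308),
    ("total", 2008, "oad", 14215, 4768077, 298, 293, 303),
    ("total", 2009, "oad", 14365, 4829800, 297, 293, 302),
    ("total", 2010, "oad", 14292, 4888946, 292, 288, 297),
    ("total", 2011, "oad", 13500, 4953217, 273, 268, 277),
    ("total", 2006, "insulin_only", 1426, 4661041, 31, 29, 32),
    ("total", 2007, "insulin_only", 1472, 4709284, 31, 30, 33),
    ("total", 2008, "insulin_only", 1628, 4768077, 34, 33, 36),
    ("total", 2009, "insulin_only", 1584, 4829800, 33, 31, 34),
    ("total", 2010, "insulin_only", 1597, 4888946, 33, 31, 34),
]

#: published prevalent-user headline figures (count, denominator, percent)
NATIONAL_PREVALENCE = {
    # any blood glucose-lowering drug, 2011, over the 2011 mean population
    "any_2011": (156_540, 4_953_217, 3.2),
    # insulins only, 2010, default 24-month washout
    "insulin_only_2010": (31_515, 4_888_946, 0.64),
    # insulins only, 2010, washout extended to six years (sensitivity)
    "insulin_only_2010_washout72": (27_927, 4_888_946, 0.57),
}


#: (stratum, year, outcome) rows whose printed rate or CI does not equal
#: round-half-away of the Wald recomputation (they differ by < 1 unit;
#: the source mixes rounding and truncation when printing)
_NOT_REPRODUCIBLE = {
    ("women", 2006, "any"),
    ("women", 2009, "any"),
    ("women", 2011, "any"),
    ("women", 2010, "oad"),
    ("women", 2008, "insulin_only"),
    ("men", 2011, "any"),
    ("men", 2007, "insulin_only"),
    ("men", 2009, "insulin_only"),
    ("total", 2006, "any"),
    ("total", 2007, "any"),
    ("total", 2008, "any"),
    ("total", 2009, "any"),
    ("total", 2006, "oad"),
    ("total", 2008, "insulin_only"),
}


def national_incidence_table() -> pd.DataFrame:
    """Printed national incident-user table (see module docstring)."""
    tab = pd.DataFrame(_ROWS, columns=_COLUMNS)
    keys = list(zip(tab["stratum"], tab["year"], tab["outcome"]))
    tab["ci_reproducible"] = [k not in _NOT_REPRODUCIBLE for k in keys]
    return tab
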