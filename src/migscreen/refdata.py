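"""Bundled reference data.

`load_migrant_list` returns the curated list of migrants reported from
recycled-HDPE milk-bottle food simulants (retention time, measured precursor
m/z, adduct, name, CAS, formula, detection fill percentage, matrix, and the
identification source/score). It doubles as a worked accuracy benchmark for
the mass arithmetic in :mod:`migscreen.chemcore` — every row carries a
printed measured precursor m/z alongside its formula and adduct — and as a
ready-made suspect list for structure-database searches.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_MIGRANTS = "rhdpe_migrants.tsv"


def load_migrant_list() -> pd.DataFrame:
    """Load the recycled-HDPE migrant reference list as a DataFrame."""
    ref = resources.files("migscreen.data").joinpath(_MIGRANTS)
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    return df
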