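"""Bundled reference tables.

``load_italian_sheep_demography`` returns the published herd-book
demographic summary of the 56 Italian sheep breeds for 2010-2024: number of
registered farms and animals in 2024, their absolute and percent change
since 2010 (or since official recognition, for breeds recognised later),
the mean yearly growth rate, Wright's effective population size from the
2024 breeding males and females, the per-generation inbreeding increase
dF% = 100/(2 Ne) (NA for the seven breeds with Ne = 0), and the FAO risk
category.  Percent-change and dF columns are as printed in the source
summary (one to two decimals; ``inf`` where the initial count was zero),
which makes the table usable as a fixture for verifying the demographic
formulas against independently published arithmetic.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["load_italian_sheep_demography"]


def load_italian_sheep_demography() -> pd.DataFrame:
    path = resources.files("flockscape.data").joinpath(
        "italian_sheep_demography_2010_2024.tsv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t", na_values=["NA"])
    df["pct_animals"] = df["pct_animals"].replace("Inf", np.inf).astype(float)
    return df
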