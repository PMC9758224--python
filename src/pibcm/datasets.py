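"""Packaged reference tables."""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_fish_activation_energies() -> pd.DataFrame:
    """Literature survey of species-specific activation energies.

    One row per published Arrhenius regression of routine/standard
    metabolic rate on inverse temperature, across 19 teleost species
    (31 fits): fitted E (eV), R², p, the assay temperatures, mean body
    weight (g) and environment (F fresh, B brackish, M marine).  The
    survey mean is 0.55 eV with extremes 0.23 (mosquitofish) and 0.96 eV
    (Nile tilapia).
    """
    with resources.files("pibcm.data").joinpath("fish_activation_energies.csv").open() as fh:
        return pd.read_csv(fh)
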