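"""Bundled reference datasets.

``load_marker_panel`` returns the published panel of 29 short-amplicon
Sumatran rhinoceros microsatellite markers (locus names, untailed primer
sequences, allele counts, M13-tailed size ranges, and the per-locus
statistics A, H_E, H_O, F_IS, P_ID, P_ID(sib) as printed, characterised on
six captive individuals).  F_IS is NA where the source table printed a
dash.  The size range includes the 18 bp M13 forward tail.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_marker_panel"]


def load_marker_panel() -> pd.DataFrame:
    """The 29-marker Sumatran rhinoceros panel as a DataFrame indexed by
    locus name."""
    ref = resources.files("msatmine.data").joinpath("sumatran_rhino_panel.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", na_values=["NA"])
    return df.set_index("locus")
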