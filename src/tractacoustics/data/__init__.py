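"""Packaged reference data."""

from importlib import resources

import pandas as pd


def reference_morphometry() -> pd.DataFrame:
    """Reference morphometry of six Estill voice qualities.

    OP/HP ratio (oropharyngeal over hypopharyngeal volume) and vocal-tract
    length L in cm for MRI-derived tracts of one professional singer
    sustaining /a:/ and /i:/ at the pitches A-flat-3 (208 Hz) and A-flat-4
    (415 Hz) in the qualities Belting, Twang, Opera, Sobbing, Speech and
    Falsetto.  Used for classification context (megaphone: OP/HP > 1;
    inverted megaphone: OP/HP < 1) and range checks.
    """
    with resources.files(__package__).joinpath("reference_morphometry.csv").open() as fh:
        return pd.read_csv(fh)
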