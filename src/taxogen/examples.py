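"""Worked-example data: the Halomonadaceae type-strain synonym survey.

Published pairwise ANI and dDDH values for the candidate conspecific
type-strain pairs of the family Halomonadaceae, used to demonstrate the
synonym-calling rule (both ANI directions >= 96% and dDDH >= 70%).  Only the
surveyed pairs carry values; all other cells are missing, which is exactly
the situation the connected-component rule is designed for: the
aquamarina-meridiana-axialensis triple emerges from pairwise evidence.

For the triple, the survey reports ranges (ANI 96.5-97.5%, dDDH 71.2-79.1%)
rather than per-pair values; the three pair values below are placed inside
those ranges (the two endpoints and a midpoint) — any in-range assignment
produces the same synonym sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ogri import OGRIMatrix

# (genome A, genome B, ANI percent, dDDH percent)
SYNONYM_SURVEY_PAIRS: list[tuple[str, str, float, float]] = [
    ("Chromohalobacter_israelensis", "Chromohalobacter_salexigens", 98.1, 83.6),
    ("Halomonas_alkaliphila", "Halomonas_humidisoli", 97.7, 80.5),
    ("Halomonas_antri", "Halomonas_sulfidivorans", 97.7, 80.2),
    ("Halomonas_aquamarina", "Halomonas_meridiana", 97.5, 79.1),
    ("Halomonas_aquamarina", "Halomonas_axialensis", 96.5, 71.2),
    ("Halomonas_meridiana", "Halomonas_axialensis", 97.0, 75.0),
    ("Halomonas_halophila", "Halomonas_salina", 100.0, 100.0),
    ("Halomonas_icarae", "Halomonas_marinisediminis", 97.4, 79.2),
    ("Halomonas_neptunia", "Halomonas_alkaliantarctica", 98.9, 91.1),
    ("Halomonas_hamiltonii", "Halomonas_johnsoniae", 97.3, 76.8),
    ("Halomonas_venusta", "Halomonas_hydrothermalis", 96.8, 73.0),
]


def synonym_survey_matrices() -> tuple[OGRIMatrix, OGRIMatrix]:
    """ANI and dDDH matrices over the surveyed type strains.

    Surveyed pairs carry the reported values (mirrored into both ANI
    directions, since single values were reported per pair); everything else
    is missing.
    """
    genomes = sorted(
        {g for a, b, _v1, _v2 in SYNONYM_SURVEY_PAIRS for g in (a, b)}
    )
    ani = pd.DataFrame(np.nan, index=genomes, columns=genomes, dtype=float)
    dddh = pd.DataFrame(np.nan, index=genomes, columns=genomes, dtype=float)
    np.fill_diagonal(ani.values, 100.0)
    np.fill_diagonal(dddh.values, 100.0)
    for a, b, v_ani, v_dddh in SYNONYM_SURVEY_PAIRS:
        ani.loc[a, b] = ani.loc[b, a] = v_ani
        dddh.loc[a, b] = dddh.loc[b, a] = v_dddh
    return (
        OGRIMatrix(kind="ANI", df=ani, directional=True,
                   params={"source": "published type-strain survey"}),
        OGRIMatrix(kind="dDDH", df=dddh,
                   params={"source": "published type-strain survey"}),
    )
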