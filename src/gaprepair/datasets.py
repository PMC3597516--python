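"""Bundled reference dataset: published strain-level summary counts.

Strain-level measurements from the mitotic gap-repair assay study this
package models (wild-type and helicase-mutant backgrounds, all
mismatch-repair-deficient): normalized mean repair efficiencies, CO/NCO
partitions of His+ transformants, and unidirectional/bidirectional class
counts among heteroduplex-detected sequenced NCOs.  Shipping these
numbers lets the full table assembly run and be checked offline.

``n_detected`` can exceed ``uni_count + bi_count``: the mph1 sgs1 double
mutant had one sequenced NCO whose heteroduplex pattern matched
Holliday-junction cleavage, counted among detected events but outside
the two classes.
"""

from __future__ import annotations

import pandas as pd

from .efficiency import build_table

#: Wild-type mean raw His+:Leu+ ratios per plasmid-mix batch, used for
#: normalization when raw ratios from both mixes are analyzed together.
REFERENCE_WT_MIX_MEANS: dict[int, float] = {1: 1.57, 2: 1.05}

#: One row per strain.  ``n_his`` is the number of His+ transformants
#: scored for plasmid stability; ``n_sequenced`` the NCOs sequenced;
#: ``n_detected`` those with plasmid heteroduplex.
REFERENCE_ROWS: list[dict] = [
    dict(strain="WT", repair_efficiency=1.00, n_transformations=36,
         co_count=41, n_his=453, n_sequenced=249,
         uni_count=141, bi_count=18, n_detected=159),
    dict(strain="mph1", repair_efficiency=1.04, n_transformations=24,
         co_count=89, n_his=462, n_sequenced=242,
         uni_count=150, bi_count=26, n_detected=176),
    dict(strain="sgs1", repair_efficiency=0.72, n_transformations=12,
         co_count=26, n_his=176, n_sequenced=285,
         uni_count=136, bi_count=13, n_detected=149),
    dict(strain="srs2", repair_efficiency=0.31, n_transformations=40,
         co_count=86, n_his=343, n_sequenced=254,
         uni_count=102, bi_count=27, n_detected=129),
    dict(strain="mph1 sgs1", repair_efficiency=0.87, n_transformations=12,
         co_count=41, n_his=186, n_sequenced=None,
         uni_count=36, bi_count=10, n_detected=47),
    dict(strain="mph1 srs2", repair_efficiency=0.55, n_transformations=11,
         co_count=52, n_his=179, n_sequenced=85,
         uni_count=38, bi_count=5, n_detected=43),
    dict(strain="srs2-860", repair_efficiency=0.80, n_transformations=12,
         co_count=26, n_his=178, n_sequenced=None,
         uni_count=29, bi_count=4, n_detected=33),
]


def load_reference_counts() -> pd.DataFrame:
    """The bundled strain-level counts as a DataFrame indexed by strain."""
    return pd.DataFrame(REFERENCE_ROWS).set_index("strain")


def reference_efficiency_table() -> pd.DataFrame:
    """Full-precision efficiency table built from the bundled counts."""
    return build_table(REFERENCE_ROWS)
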