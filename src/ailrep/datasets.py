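"""Bundled reference data.

``paired_locus_table`` ships the per-locus discovery/replication summary
statistics (p, allele frequency, beta, se) for the twelve lead loci of a
two-cohort mouse advanced-intercross GWAS, used by examples and the
acceptance checks. ``coat_color`` marks the two Mendelian coat loci per
discovery direction.
"""

from __future__ import annotations

import pandas as pd

_ROWS = [
    # discovery_cohort, phenotype, snp_id, disc_p, disc_af, disc_beta, disc_se,
    #                              rep_p,  rep_af,  rep_beta,  rep_se, coat
    ("A", "body_weight", "chr4.66414508", 8.58e-8, 0.419, -0.25, 0.05,
     3.55e-3, 0.406, -0.13, 0.04, False),
    ("A", "body_weight", "chr6.81405109", 6.22e-6, 0.497, 0.21, 0.05,
     3.52e-2, 0.518, 0.09, 0.04, False),
    ("A", "body_weight", "chr14.79312393", 7.45e-6, 0.514, -0.20, 0.04,
     2.37e-2, 0.566, -0.10, 0.04, False),
    ("A", "coat_albino", "chr7.87642045", 5.00e-106, 0.432, -0.58, 0.02,
     1.59e-162, 0.388, -0.61, 0.02, True),
    ("A", "coat_agouti", "chr2.154464466", 9.43e-191, 0.129, 0.94, 0.01,
     5.7e-93, 0.207, 0.72, 0.03, True),
    ("A", "locomotor_day1", "chr19.21812298", 3.98e-7, 0.461, -0.36, 0.07,
     4.55e-1, 0.502, -0.05, 0.06, False),
    ("A", "locomotor_day2", "chr8.17410225", 5.65e-6, 0.171, 0.42, 0.09,
     8.34e-1, 0.202, 0.02, 0.08, False),
    ("B", "body_weight", "chr1.89192209", 6.42e-6, 0.220, 0.22, 0.05,
     5.16e-2, 0.276, 0.10, 0.05, False),
    ("B", "body_weight", "chr14.82586326", 1.48e-6, 0.658, -0.22, 0.04,
     3.08e-5, 0.575, -0.19, 0.05, False),
    ("B", "coat_albino", "chr7.87255156", 3.37e-166, 0.389, -0.62, 0.02,
     7.80e-97, 0.444, -0.57, 0.02, True),
    ("B", "coat_agouti", "chr2.155091628", 1.78e-115, 0.218, 0.74, 0.02,
     1.51e-185, 0.135, 0.90, 0.01, True),
    ("B", "locomotor_day2", "chr15.67627183", 3.33e-6, 0.461, 0.30, 0.06,
     2.07e-1, 0.522, -0.08, 0.07, False),
]

_COLUMNS = [
    "discovery_cohort", "phenotype", "snp_id",
    "disc_p", "disc_af", "disc_beta", "disc_se",
    "rep_p", "rep_af", "rep_beta", "rep_se", "coat_color",
]


def paired_locus_table() -> pd.DataFrame:
    """Twelve paired discovery/replication lead-locus summary rows."""
    return pd.DataFrame(_ROWS, columns=_COLUMNS)
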