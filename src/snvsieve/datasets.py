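"""Published input tables used by the benchmarks and worked examples.

``miller_exome_counts`` holds the per-sample, per-consequence SNV counts of
the eight unrelated exomes (four Illumina GAII, four HiSeq) that parameterize
the semi-synthetic Miller-syndrome benchmark.  ``schinzel_giedion_candidates``
holds the published top-ten candidate-gene table from the Schinzel-Giedion
syndrome exome study (four patients; SETBP1 is the causative gene), used as a
ranking worked example.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

#: Consequence categories generated/counted by the synthetic-exome machinery.
COUNT_CATEGORIES = (
    "essential_splice",
    "nonsense",
    "nonsynonymous",
    "synonymous",
    "utr",
)

_MILLER_COUNTS = """\
sample	essential_splice	nonsense	nonsynonymous	synonymous	utr
S1	178	99	8864	8409	3839
S2	120	88	7468	7214	3216
S3	137	95	8039	7756	3080
S4	134	108	8246	8065	3264
S5	47	101	7925	8500	4264
S6	45	60	6715	7676	1443
S7	49	68	6487	7347	1421
S8	44	68	6560	7597	1367
"""

_SCHINZEL_GIEDION_TOP10 = """\
rank	unit_id	n_samples	n_unique_variants	n_total_variants	haploinsufficiency	max_phylop_mammal
1	SETBP1	4	2	3	0.721	3.455
2	CDC27	4	5	13		3.106
3	CTBP2	4	3	8		2.805
4	PRB1	4	2	5		1.458
5	KIR2DL1	4	1	2		1.05
6	FLG	4	5	6		1.034
7	OR11H1	4	0	1		0.856
8	KIR2DL3	4	4	6		-0.326
9	CDCP2	4	0	1		-0.365
10	NBPF12	4	0	2		-0.411
"""


def miller_exome_counts() -> pd.DataFrame:
    """Per-sample, per-consequence SNV counts of the eight published exomes.

    Rows are sample identifiers S1..S8, columns the five counted consequence
    classes.  These counts are the study conditions of the semi-synthetic
    benchmark: shuffling must preserve them exactly and the synthetic
    generator reproduces them cell for cell.
    """
    df = pd.read_csv(io.StringIO(_MILLER_COUNTS), sep="\t", index_col="sample")
    return df[list(COUNT_CATEGORIES)].astype(np.int64)


def schinzel_giedion_candidates() -> pd.DataFrame:
    """Published top-ten candidate genes of the Schinzel-Giedion case study.

    Columns match the ranked-table export: rank, unit_id, n_samples,
    n_unique_variants, n_total_variants, haploinsufficiency (NaN where not
    predicted) and max PhyloP over the placental-mammal alignment.
    """
    return pd.read_csv(io.StringIO(_SCHINZEL_GIEDION_TOP10), sep="\t")
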