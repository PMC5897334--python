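"""Published reference evidence panel of 15 coordinated miRNA pairs.

The table below is the pair-level evidence reported by a paired green-tea
exposure study of human oral (lingual) epithelium: 11 tobacco-smoking
subjects sampled at baseline and after 4 weeks of green-tea consumption,
profiled on a 372-assay RT-qPCR miRNA panel.  Each row carries, for one
miRNA pair, the two paired-t differential-expression p-values (``p_de1``,
``p_de2``), the Spearman correlation across all 22 samples (``cc``) and its
tail probability (``p_cc``), plus the combined Stouffer z-score, its normal
p-value and scan-level FDR as printed in the study's results table.

These rows serve two purposes: (1) as input to
:func:`coexpair.pairs.pair_scan_from_stats`, re-scoring the published
evidence without the (undeposited) raw expression data; (2) as a worked
ground truth for validating the combination statistic, the Spearman tail
convention, and the hub graph (15 pairs over 18 miRNAs, with miR-181a-5p
co-expressed with 7 partners and miR-301a-3p with 3).
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = ["load_reference_pairs", "REFERENCE_N_SAMPLES"]

#: Sample count underlying the reference panel (11 subjects x 2 timepoints).
REFERENCE_N_SAMPLES = 22

# Columns: pair ids; component p-values; Spearman cc and its tail p;
# published combined z, its p, and scan FDR (the last three are the study's
# printed outputs, retained for cross-checks — not inputs to re-scoring).
_REFERENCE_TSV = """\
mirna1	mirna2	p_de1	p_de2	cc	p_cc	published_z	published_p_z	published_fdr_z
hsa-miR-328-3p	hsa-miR-181a-5p	3.61e-1	4.67e-2	0.774	1.18e-5	4.28	9.28e-6	7.21e-3
hsa-miR-199b-5p	hsa-miR-181a-5p	4.90e-1	4.67e-2	0.844	3.94e-7	4.73	1.14e-6	2.43e-3
hsa-miR-378a-3p	hsa-miR-375	3.07e-2	6.70e-2	0.693	1.76e-4	4.29	8.78e-6	7.15e-3
hsa-miR-425-5p	hsa-miR-181a-5p	2.11e-1	4.67e-2	0.819	1.55e-6	4.82	7.16e-7	1.75e-3
hsa-miR-423-3p	hsa-miR-484	8.03e-2	2.53e-2	0.684	2.25e-4	4.24	1.14e-5	8.27e-3
hsa-miR-301a-3p	hsa-miR-30e-5p	4.29e-2	5.24e-1	0.794	5.04e-6	4.28	9.23e-6	7.21e-3
hsa-miR-301a-3p	hsa-miR-30e-3p	4.29e-2	3.61e-1	0.886	2.08e-8	5.32	5.07e-8	3.47e-4
hsa-miR-301a-3p	hsa-miR-182-5p	4.29e-2	2.78e-1	0.855	1.95e-7	5.08	1.85e-7	7.94e-4
hsa-miR-150-5p	hsa-miR-181a-5p	4.09e-1	4.67e-2	0.771	1.35e-5	4.21	1.30e-5	9.06e-3
hsa-miR-145-5p	hsa-miR-181a-5p	1.87e-1	4.67e-2	0.788	6.76e-6	4.60	2.11e-6	3.79e-3
hsa-miR-145-5p	hsa-miR-766-3p	1.87e-1	4.47e-2	0.722	7.38e-5	4.16	1.62e-5	9.92e-3
hsa-miR-181a-5p	hsa-miR-766-3p	4.67e-2	4.47e-2	0.715	9.10e-5	4.43	4.62e-6	4.60e-3
hsa-miR-181a-5p	hsa-miR-142-3p	4.67e-2	1.30e-1	0.770	1.41e-5	4.56	2.52e-6	3.87e-3
hsa-miR-766-3p	hsa-miR-142-3p	4.47e-2	1.30e-1	0.753	2.65e-5	4.45	4.23e-6	4.52e-3
hsa-miR-340-5p	hsa-miR-410-3p	1.27e-1	2.86e-2	-0.812	2.27e-6	4.99	3.08e-7	9.59e-4
"""


def load_reference_pairs() -> pd.DataFrame:
    """The 15-pair reference evidence panel as a DataFrame.

    Columns ``mirna1, mirna2, p_de1, p_de2, cc, p_cc`` are inputs in the
    layout :func:`coexpair.pairs.pair_scan_from_stats` accepts;
    ``published_z``, ``published_p_z`` and ``published_fdr_z`` hold the
    study's printed combined statistics for cross-checking.
    """
    return pd.read_csv(io.StringIO(_REFERENCE_TSV), sep="\t")
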