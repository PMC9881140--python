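"""Package-wide default parameters.

These are the published defaults of the method: every statistic keeps the
value used in the original analyses unless the caller overrides it.
"""

#: Links per bin when evaluating a ranked link list against a gold standard.
LLS_BIN_SIZE = 1000

#: Minimum pooled null centrality scores for the hub significance test.
HUB_N_NULL = 10_000

#: Random degree-matched gene sets for the compactness (connectivity) test.
CONNECTIVITY_N_NULL = 10_000

#: Relative tolerance on unweighted degree when sampling matched genes (+/-20%).
DEGREE_TOLERANCE = 0.2

#: Pooled null diffPR values for the differential-hub permutation test.
DIFF_N_NULL = 1_000_000

#: Fraction of nonzero-diffPR genes reported as top differential hubs (top 5%).
TOP_DIFF_FRACTION = 0.05

#: Percentile-rank gate and |diffPR| cut for lost/gained hub classification.
PR_CUT = 0.7
DIFF_CUT = 0.7

#: Benjamini-Hochberg FDR threshold for hub calls.
FDR_CUT = 0.05

#: Cell-type strata smaller than this are skipped when building networks.
MIN_CELLS = 50

#: Gene-activity thresholding: retain the top fraction of genes per cell type.
THRESHOLD_MODE = "percentile"
THRESHOLD = 0.5

#: Swap attempts per degree-preserving rewired replicate, as a multiple of |E|.
SWAPS_PER_EDGE = 10
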