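"""Package-wide default parameter values.

Every module and CLI subcommand draws its defaults from here, so the
values can be asserted in one place and overridden consistently.
"""

#: Sliding-window size, in bins, for the windowed spectral decomposition.
WINDOW = 15

#: Boundary-score cutoff: a bin with score >= this is a called boundary.
BOUNDARY_THRESHOLD = 3.0

#: Differential-score cutoff: |DB| >= this marks a differential bin.
DIFF_THRESHOLD = 2.0

#: Maximum distance, in bins, for a boundary to count as "shifted".
SHIFT_BINS = 5

#: Minimum fraction of non-zero in-window contacts for an informative bin.
INFORMATIVE_FRAC = 0.2

#: Flank, in bp, added to each side of a boundary bin for colocalization.
FLANK_BP = 50_000

#: Number of permutations for the colocalization enrichment test.
N_PERMUTATIONS = 10_000
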