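"""Published summary counts used for arithmetic cross-checks.

These are the study's reported tallies (gene counts, not data): inputs to
the overlap arithmetic in :mod:`regentc.motifs`, kept in one place so the
derived percentages are computed rather than hard-coded.
"""

#: Dynamic genes per paradigm (sucrose shock, posterior halves, anterior halves).
DYNAMIC_SUCROSE = 4323
DYNAMIC_POSTERIOR = 1020
DYNAMIC_ANTERIOR = 229

#: Total differentially expressed genes across the six module tables, and
#: the total number of gene models in the genome.
DE_GENES_TOTAL = 4775
GENOME_GENE_MODELS = 34494

#: Cycloheximide comparison within the OA-specific module.
OA_MODULE_TOTAL = 431
CHX_UNAFFECTED = 21
CHX_AFFECTED = 411

#: Per-cluster average correlation values (reported on a scale consistent
#: with mean atanh(r): note values above 1).
CLUSTER_MEAN_CORRELATIONS = (0.72, 1.54, 2.31, -0.22, 0.81)

#: Zebrafish optic-nerve regeneration comparison: orthologs found, orthologs
#: differentially expressed, orthologs in the bisection+general classes, and
#: the size of those two classes.
ZEBRAFISH_ORTHOLOGS = 606
ZEBRAFISH_ORTHOLOGS_DE = 110
ZEBRAFISH_IN_BISECTION_GENERAL = 7
BISECTION_GENERAL_CLASS_SIZE = 123

#: Motif target tallies among dynamic genes.
E2F_TARGETS = 13
PUM_TARGETS = 34
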