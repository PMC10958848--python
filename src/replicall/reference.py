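"""Published reference benchmark for the within-center consensus sweep.

These are the reported detection counts and scores for the FD-center
replicates of the SEQC2 tumor/normal exome study: six mapper x caller
pipelines, consensus thresholds m >= 1..3, scored against the 1,159
high-confidence exome SNVs.  They serve as golden values for the metric
formulas — every row satisfies TP + FN = 1159, and the printed
precision/recall/F1 equal the formulas applied to TP/FP/FN at 3 decimals.
"""

from __future__ import annotations

from typing import List, NamedTuple

#: Size of the high-confidence exome SNV truth set the rows are scored against.
TRUTH_SIZE = 1159


class ReferenceRow(NamedTuple):
    pipeline: str
    m: int
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float


FD_WITHIN_CENTER: List[ReferenceRow] = [
    ReferenceRow("bwa_mutect", 1, 1003, 525, 156, 0.656, 0.865, 0.747),
    ReferenceRow("bwa_mutect", 2, 900, 2, 259, 0.998, 0.777, 0.873),
    ReferenceRow("bwa_mutect", 3, 749, 0, 410, 1.000, 0.646, 0.785),
    ReferenceRow("bowtie_mutect", 1, 988, 565, 171, 0.636, 0.852, 0.729),
    ReferenceRow("bowtie_mutect", 2, 875, 2, 284, 0.998, 0.755, 0.860),
    ReferenceRow("bowtie_mutect", 3, 727, 0, 432, 1.000, 0.627, 0.771),
    ReferenceRow("bwa_strelka", 1, 1037, 2808, 122, 0.270, 0.895, 0.414),
    ReferenceRow("bwa_strelka", 2, 927, 20, 232, 0.979, 0.800, 0.880),
    ReferenceRow("bwa_strelka", 3, 785, 3, 374, 0.996, 0.677, 0.806),
    ReferenceRow("bowtie_strelka", 1, 937, 539, 222, 0.635, 0.808, 0.711),
    ReferenceRow("bowtie_strelka", 2, 792, 5, 367, 0.994, 0.683, 0.810),
    ReferenceRow("bowtie_strelka", 3, 643, 3, 516, 0.995, 0.555, 0.712),
    ReferenceRow("bwa_ss", 1, 948, 1013, 211, 0.483, 0.818, 0.608),
    ReferenceRow("bwa_ss", 2, 816, 96, 343, 0.895, 0.704, 0.788),
    ReferenceRow("bwa_ss", 3, 677, 9, 482, 0.987, 0.584, 0.734),
    ReferenceRow("bowtie_ss", 1, 918, 1009, 241, 0.476, 0.792, 0.595),
    ReferenceRow("bowtie_ss", 2, 793, 97, 366, 0.891, 0.684, 0.774),
    ReferenceRow("bowtie_ss", 3, 661, 15, 498, 0.978, 0.570, 0.720),
]
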