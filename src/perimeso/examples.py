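"""Worked example: the published 12-case peritoneal malignant mesothelioma
cohort's BAP1 evidence.

Each case was assayed by some subset of copy-number array (A), whole-exome
sequencing of a tumor/normal pair (E) and targeted BAP1 amplicon sequencing
(T).  The rows below encode the reported per-sample evidence — germline
loss-of-function variant, copy-number loss over BAP1 (size, whole-chromosome
or subclonal) and somatic mutations with per-assay allelic fractions — as
inputs to the integration stage, which derives each sample's category and
the cohort decomposition.
"""

from __future__ import annotations

from .integrate import (LossEvidence, SampleGeneStatus, SomaticEvidence,
                        status_from_evidence)

AET = ("array", "exome", "targeted")
AT = ("array", "targeted")
T = ("targeted",)


def bap1_case_evidence() -> list[dict]:
    """Evidence rows for the 12 cases (assays, germline variant, loss,
    somatic mutations with allelic fraction per assay)."""
    mb = 1_000_000
    return [
        dict(sample="AA1844T", assays=AET, germline=None,
             loss=LossEvidence(subclonal=True),
             mutations=[SomaticEvidence("Q393*", (("exome", 0.12),
                                                  ("targeted", 0.20)))]),
        dict(sample="AA1968T", assays=AET, germline=None, loss=None,
             mutations=[]),
        dict(sample="AA2273T", assays=AET, germline=None, loss=None,
             mutations=[SomaticEvidence("K453*", (("exome", 0.48),
                                                  ("targeted", 0.51)))]),
        dict(sample="AA2463T", assays=AET, germline="Y44*",
             loss=LossEvidence(whole_chromosome="3"), mutations=[]),
        dict(sample="AA2476T", assays=AET, germline=None,
             loss=LossEvidence(size_bp=15 * mb),
             mutations=[SomaticEvidence("I71fs", (("exome", 0.14),
                                                  ("targeted", 0.20)))]),
        dict(sample="AA2528T", assays=AET, germline=None, loss=None,
             mutations=[]),
        dict(sample="AA2253T", assays=AET, germline=None,
             loss=LossEvidence(size_bp=int(0.34 * mb)), mutations=[]),
        dict(sample="AA2489T", assays=AT, germline=None,
             loss=LossEvidence(size_bp=54 * mb), mutations=[]),
        dict(sample="AA2617T", assays=AT, germline=None, loss=None,
             mutations=[SomaticEvidence("A95fs", (("targeted", 0.39),))]),
        dict(sample="AA2830T", assays=T, germline=None, loss=None,
             mutations=[]),
        dict(sample="AA2627T", assays=T, germline=None, loss=None,
             mutations=[SomaticEvidence("Q684*", (("targeted", 0.50),))]),
        dict(sample="AA2819T", assays=T, germline=None, loss=None,
             mutations=[]),
    ]


def bap1_case_statuses(purity: float = 0.7) -> list[SampleGeneStatus]:
    """The 12 per-sample statuses derived from the encoded evidence."""
    return [status_from_evidence(r["sample"], r["assays"], r["germline"],
                                 r["loss"], r["mutations"], purity=purity)
            for r in bap1_case_evidence()]
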