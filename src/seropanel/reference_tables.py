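"""Published reference values bundled for worked examples.

``CANDIDATE_TABLE`` is the reported consensus autoantigen panel for the
AIH protein-array screen (per-antigen ensemble-mean VIP and whole-percent
recognition frequencies in healthy donors and AIH patients) and
``VALIDATION_COUNTS`` the validation-phase positivity counts that the
reported sensitivities/specificities are back-calculated from.  They are
inputs for the worked examples and acceptance checks, never outputs of
this package's own computations.
"""

from __future__ import annotations

from io import StringIO

import numpy as np
import pandas as pd

_CANDIDATE_TSV = """\
description	protein_id	vip	hd_pct	aih_pct
Interleukin 4 receptor	IL4R	1.57	0	67
Lysozyme g-like protein 1 Precursor	LYG1	1.38	4	73
Uncharacterized protein C19orf47	C19orf47	2.04	4	80
Solute carrier family 22 member 23	SLC22A23	1.22	0	60
Putative uncharacterized protein	UNQ5830	1.94	0	80
Putative uncharacterized protein DKFZp667F0711	AL137145.1	1.91	1	87
Hypothetical protein LOC648852	LOC648852	1.32	0	60
Putative uncharacterized protein	LOC646100	1.68	0	73
Uncharacterized protein C17orf99 Precursor	C17orf99	1.46	0	73
Uncharacterized protein C17orf99 Precursor (2)	C17orf99-2	1.6	0	67
UPF0631 protein HSD24	AC130289.1	1.23	0	60
Transmembrane 95 Precursor	TMEM95	1.12	0	60
Cys-rich secr. prot. LCCL domain-containing 2	CRISPLD2	1.21	1	60
Ankyrin repeat domain- protein 43 Precursor	ANKRD43	1.27	0	60
RPE-spondin Precursor	C8orf84	1.42	0	67
Carboxypeptidase-like protein X2 Precursor	CPXM2	1.83	0	80
DnaJ homolog subfamily C member 30	DNAJC30	1.44	4	73
Chondroadherin-like Precursor	CHADL	1.14	4	73
Protein APCDD1-like Precursor	APCDD1L	1.49	0	73
Putative uncharacterized protein	AC016586	1.45	0	60
VGSA5840	AC060225	1.3	0	60
AHPA9419	UNQ9419	1.36	0	53
Calcium homeostasis modulator protein 3	CALHM3	1.25	0	80
T cell receptor beta variable 7	A0A598	1.24	0	53
Putative uncharacterized protein	AC007245	1.33	0	67
Thymic stromal cotransporter homolog	SLC46A2	1.21	0	67
Inhibin beta E chain Precursor	INHBE	1.51	0	60
WFDC10B Precursor	WFDC10B	1.1	0	60
R-spondin-3 Precursor	RSPO3	1.08	0	53
Membrane progestin receptor alpha	PAQR7	1.5	0	80
Chondroadherin Precursor	CHAD	1.65	1	87
"""


def candidate_table() -> pd.DataFrame:
    """The reported 31-antigen candidate panel (VIP, HD%, AIH%)."""
    return pd.read_csv(StringIO(_CANDIDATE_TSV), sep="\t")


# validation-phase positivity counts (n_AIH = 40, n_HD = 35) backing the
# reported sensitivities/specificities: positives per group
VALIDATION_COUNTS = {
    "UNQ9419": {"AIH": 18, "HD": 0},   # SE 45%, SP 100%
    "CHAD": {"AIH": 21, "HD": 4},      # SE 53%, SP 89%
}
VALIDATION_N = {"AIH": 40, "HD": 35}

# discovery-phase worked example: CHAD recognized by 13 of 15 AIH sera
DISCOVERY_CHAD_AIH = {"positive": 13, "n": 15}


def calls_from_counts(
    marker: str, overlap: str = "nested"
) -> tuple[pd.Series, pd.Series]:
    """Reconstruct per-sample calls and labels from the validation counts.

    With only marginal counts available, positives are assigned to the
    first samples of each group ("nested"), which makes any two markers'
    positive sets maximally overlapping — the conservative choice for an
    or-rule combination (the union is as small as the counts allow).
    """
    counts = VALIDATION_COUNTS[marker]
    labels, calls = [], []
    for group, n in VALIDATION_N.items():
        k = counts[group]
        labels.extend([group] * n)
        calls.extend([1] * k + [0] * (n - k))
    idx = [f"{g}{i:03d}" for g in VALIDATION_N for i in range(VALIDATION_N[g])]
    return (
        pd.Series(np.array(calls, dtype=np.int8), index=idx),
        pd.Series(labels, index=idx),
    )
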