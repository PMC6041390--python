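"""Packaged datasets: the 31-hybridoma heavy-chain table and the germline.

The hybridoma table transcribes the published V-region summary of 31 IgG
anti-dsDNA hybridomas from three double-deficient mice: per row the
hybridoma id, printed clone label, isotype, V/J gene calls, total and
non-silent mutation counts, the IMGT CDR3 amino-acid sequence and the
printed Kabat-convention arginine count. Nucleotide sequences were not
published, so mutation counts are carried as annotations and the printed
clone labels serve as the ground-truth clonal partition.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .germline import GermlineDB, load_germline

#: the published panel-wide CDR3 residue denominator, carried as a fixture
#: annotation (it is not the sum of the printed CDR3 lengths under either
#: delineation; see docs/methods.md)
PUBLISHED_CDR3_RESIDUE_TOTAL = 289
PUBLISHED_CDR3_ARG_TOTAL = 47


@dataclass(frozen=True)
class PanelRecord:
    """One hybridoma row of the published V-region summary."""

    record_id: str
    mouse_id: str
    clone_label: str
    isotype: str
    v_call: str
    j_call: str
    mutations_total: int
    mutations_nonsilent: int
    cdr3_aa_imgt: str
    n_arg_kabat_printed: int


def _data_path(name: str):
    return resources.files("ighclone").joinpath("data", name)


def load_hybridoma_panel(path=None) -> list[PanelRecord]:
    """Load the packaged hybridoma table (or a user-supplied copy).

    Raises if the table does not contain exactly 31 well-formed rows.
    """
    source = path if path is not None else _data_path("hybridoma_panel.tsv")
    with resources.as_file(source) if path is None else _nullcontext(source) as p:
        df = pd.read_csv(p, sep="\t", dtype=str)
    expected = {
        "hybridoma", "mouse_id", "clone_label", "isotype", "v_call", "j_call",
        "mutations_total", "mutations_nonsilent", "cdr3_aa_imgt", "n_arg_kabat_printed",
    }
    missing = expected - set(df.columns)
    if missing:
        raise ValueError(f"hybridoma table missing columns {sorted(missing)}")
    if len(df) != 31:
        raise ValueError(f"hybridoma table must have 31 rows, found {len(df)}")
    return [
        PanelRecord(
            record_id=row.hybridoma,
            mouse_id=row.mouse_id,
            clone_label=row.clone_label,
            isotype=row.isotype,
            v_call=row.v_call,
            j_call=row.j_call,
            mutations_total=int(row.mutations_total),
            mutations_nonsilent=int(row.mutations_nonsilent),
            cdr3_aa_imgt=row.cdr3_aa_imgt,
            n_arg_kabat_printed=int(row.n_arg_kabat_printed),
        )
        for row in df.itertuples()
    ]


class _nullcontext:
    def __init__(self, value):
        self.value = value

    def __enter__(self):
        return self.value

    def __exit__(self, *exc):
        return False


def load_packaged_germline() -> GermlineDB:
    """Load the packaged synthetic V/J reference (10 V + 4 J genes)."""
    with resources.as_file(_data_path("germline.fasta")) as fasta:
        with resources.as_file(_data_path("germline_anchors.tsv")) as anchors:
            return load_germline(fasta, anchors)
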