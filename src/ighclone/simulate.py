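"""Synthetic data with known truth for every pipeline stage.

The repertoire generator emulates the statistical structure of a panel of
clonally expanded, somatically mutated hybridomas: per mouse, a set of
clones each founded by one V-(junction)-J rearrangement, diversified by
point substitutions either independently from the founder (star, the
"bush-like" genealogy) or sequentially along a chain (ladder, stepwise
maturation). Junction codons can be biased toward arginine to emulate
anti-DNA CDR3 selection, and isotypes are drawn IgG2c-heavy.

Each founder is V + untemplated insert + full J; the junction (CDR3)
spans the insert plus the J-encoded tail before the W(F)GxG tryptophan,
with a total length drawn between 27 and 42 nt. SHM substitutions are
applied to the framework V/J-templated regions only; the junction stays
mutation-free by default, so the planted CDR3 is exactly recoverable and
clone membership is unambiguous (``mutate_junction`` enables CDR3
diversification). All randomness flows from one seeded generator: the
same seed yields byte-identical FASTA/TSV output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .germline import GermlineDB
from .serology import CtTable, DilutionSeries, StandardCurve

ISOTYPE_PROBS_DEFAULT = {"IgG2c": 25 / 31, "IgG2b": 5 / 31, "IgG3": 1 / 31}
# clone-size mass matching the observed hybridoma panel (sizes 1-6)
CLONE_SIZE_DIST_DEFAULT = {1: 0.50, 2: 0.14, 3: 0.22, 4: 0.04, 5: 0.04, 6: 0.06}

_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = sorted(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
)
_ARG_CODONS = {c for c in _SENSE_CODONS if str(Seq(c).translate()) == "R"}
_BASES = "ACGT"


@dataclass
class SimConfig:
    seed: int
    n_mice: int = 3
    clones_per_mouse: int = 7
    clone_size_dist: dict[int, float] = field(default_factory=lambda: dict(CLONE_SIZE_DIST_DEFAULT))
    topology_mode: str = "mixed"  # star | ladder | mixed
    mut_rate: float = 0.005  # per-site substitution probability per lineage step
    arg_selection_weight: float = 1.0  # multiplicative preference for R codons
    isotype_probs: dict[str, float] = field(default_factory=lambda: dict(ISOTYPE_PROBS_DEFAULT))
    junction_len_nt: tuple[int, int] = (27, 42)  # CDR3 length bounds, multiples of 3
    mutate_junction: bool = False

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.topology_mode not in ("star", "ladder", "mixed"):
            raise ValueError(f"unknown topology_mode {self.topology_mode!r}")
        for name, dist in (("clone_size_dist", self.clone_size_dist), ("isotype_probs", self.isotype_probs)):
            total = sum(dist.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"{name} must sum to 1, sums to {total}")
            if any(p < 0 for p in dist.values()):
                raise ValueError(f"{name} has negative mass")
        if not (0 <= self.mut_rate < 1):
            raise ValueError("mut_rate must be in [0, 1)")
        if self.arg_selection_weight <= 0:
            raise ValueError("arg_selection_weight must be positive")
        lo, hi = self.junction_len_nt
        if lo % 3 or hi % 3 or lo > hi or lo < 3:
            raise ValueError("junction_len_nt bounds must be positive multiples of 3")


@dataclass
class SimRecord:
    record_id: str
    mouse_id: str
    isotype: str
    nt_seq: str


@dataclass
class SimResult:
    records: list[SimRecord]
    truth: pd.DataFrame  # one row per record
    config: SimConfig

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for rec in self.records:
                fh.write(f">{rec.record_id}\n")
                for i in range(0, len(rec.nt_seq), 60):
                    fh.write(rec.nt_seq[i : i + 60] + "\n")

    def to_truth_tsv(self, path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)


def _draw_insert(rng: np.random.Generator, config: SimConfig, j_head_codons: int) -> str:
    """Untemplated insert so that insert + J head spans the junction bounds.

    Codons are drawn from the 61 sense codons (stop-free by construction),
    reweighted toward the six arginine codons by ``arg_selection_weight``.
    """
    lo, hi = config.junction_len_nt
    cdr3_codons = int(rng.choice(np.arange(lo // 3, hi // 3 + 1)))
    n_codons = max(cdr3_codons - j_head_codons, 1)
    weights = np.array(
        [config.arg_selection_weight if c in _ARG_CODONS else 1.0 for c in _SENSE_CODONS]
    )
    weights /= weights.sum()
    codons = rng.choice(_SENSE_CODONS, size=n_codons, p=weights)
    return "".join(codons)


def _mutate(
    rng: np.random.Generator,
    seq: list[str],
    mutable: np.ndarray,
    rate: float,
    frozen: set[int],
) -> list[int]:
    """Substitute bases in-place at Bernoulli(rate) sites; returns positions."""
    hits = [int(p) for p in np.nonzero(rng.random(len(seq)) < rate)[0] if mutable[p] and p not in frozen]
    for p in hits:
        alternatives = [b for b in _BASES if b != seq[p]]
        seq[p] = alternatives[int(rng.integers(3))]
    return hits


def _serialize_mutations(muts: list[tuple[str, int, str]]) -> str:
    return ";".join(f"{r}:{p}:{b}" for r, p, b in sorted(muts))


def parse_truth_mutations(serialized: str) -> list[tuple[str, int, str]]:
    if not serialized:
        return []
    out = []
    for item in serialized.split(";"):
        region, pos, base = item.split(":")
        out.append((region, int(pos), base))
    return out


def simulate_repertoire(config: SimConfig, db: GermlineDB) -> SimResult:
    """Generate a clonally structured, SHM-diversified heavy-chain set.

    Each clone draws a V and J gene, an in-frame stop-free junction
    (becoming the clone's CDR3, planted between the Cys104 and Trp118
    anchors), an isotype and a size; members then diversify by the
    configured topology. The truth table records, per record, the donor
    genes, planted junction/CDR3, mutation list and clone assignment.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    v_genes = db.by_segment("V")
    j_genes = db.by_segment("J")
    sizes = sorted(config.clone_size_dist)
    size_p = np.array([config.clone_size_dist[s] for s in sizes], dtype=float)
    isotypes = sorted(config.isotype_probs)
    iso_p = np.array([config.isotype_probs[i] for i in isotypes], dtype=float)

    records: list[SimRecord] = []
    truth_rows: list[dict] = []
    for mi in range(1, config.n_mice + 1):
        mouse_id = f"mouse{mi}"
        for ci in range(1, config.clones_per_mouse + 1):
            v = v_genes[int(rng.integers(len(v_genes)))]
            j = j_genes[int(rng.integers(len(j_genes)))]
            j_head_nt = 3 * j.trp118_codon_offset
            insert = _draw_insert(rng, config, j.trp118_codon_offset)
            founder = v.nt_seq + insert + j.nt_seq
            v_len, ins_len = len(v.nt_seq), len(insert)
            cdr3_len = ins_len + j_head_nt  # insert plus the J-encoded tail
            mutable = np.ones(len(founder), dtype=bool)
            if not config.mutate_junction:
                mutable[v_len : v_len + cdr3_len] = False
            size = int(rng.choice(sizes, p=size_p))
            isotype = str(rng.choice(isotypes, p=iso_p))
            mode = config.topology_mode
            if mode == "mixed":
                mode = "star" if rng.random() < 0.5 else "ladder"
            clone_truth_id = f"{mouse_id}_t{ci}"

            def region_of(p: int) -> tuple[str, int] | None:
                if p < v_len:
                    return "V", p
                if p < v_len + ins_len:
                    return None  # untemplated insert: no germline coordinate
                return "J", p - v_len - ins_len

            chain = list(founder)
            inherited: list[int] = []
            for k in range(1, size + 1):
                if mode == "star":
                    member = list(founder)
                    hits = _mutate(rng, member, mutable, config.mut_rate, frozen=set())
                    positions = hits
                else:  # ladder: inherit predecessor's state, add new sites
                    hits = _mutate(rng, chain, mutable, config.mut_rate, frozen=set(inherited))
                    inherited.extend(hits)
                    member = list(chain)
                    positions = list(inherited)
                seq = "".join(member)
                muts = [
                    (*loc, seq[p])
                    for p in sorted(positions)
                    if seq[p] != founder[p] and (loc := region_of(p)) is not None
                ]
                record_id = f"m{mi}_c{ci}_s{k}"
                records.append(SimRecord(record_id, mouse_id, isotype, seq))
                cdr3_nt = seq[v_len : v_len + cdr3_len]
                truth_rows.append(
                    {
                        "record_id": record_id,
                        "mouse_id": mouse_id,
                        "clone_id_true": clone_truth_id,
                        "v_call_true": v.name,
                        "j_call_true": j.name,
                        "isotype": isotype,
                        "topology_mode": mode,
                        "insert_nt": insert,
                        "cdr3_nt_true": cdr3_nt,
                        "cdr3_aa_true": str(Seq(cdr3_nt).translate()),
                        "n_mut_true": len(muts),
                        "mutations_true": _serialize_mutations(muts),
                    }
                )
    truth = pd.DataFrame(truth_rows)
    return SimResult(records=records, truth=truth, config=config)


# --- ELISA / qPCR generators -------------------------------------------------

OD_MAX = 2.5
OD_MIN = 0.05
EC50_STANDARD = 1600.0
HILL = 1.5


def _sigmoid_od(dilution: np.ndarray, titer_factor: float) -> np.ndarray:
    """Parallel log-logistic OD curve; titer_factor shifts it in dilution."""
    d = np.asarray(dilution, dtype=float) / titer_factor
    return OD_MIN + (OD_MAX - OD_MIN) / (1.0 + (d / EC50_STANDARD) ** HILL)


def simulate_elisa(
    true_titers: dict[str, float],
    seed: int,
    noise_sd: float = 0.02,
    n_sample_dilutions: int = 10,
    n_standard_dilutions: int = 8,
) -> tuple[dict[str, DilutionSeries], StandardCurve]:
    """Synthetic ELISA plate: standard pool plus samples with known titers.

    The standard runs 1/2 serial dilutions from 1/200, samples from 1/100.
    A sample with titer factor f is the standard curve shifted by log(f) in
    log-dilution, plus Gaussian OD noise. With the default anchor (1/200 =
    100 RU) the recovered RU of a factor-f sample is 100 f.
    """
    if any(f <= 0 for f in true_titers.values()):
        raise ValueError("titer factors must be positive")
    rng = np.random.default_rng(seed)
    std_dil = 200.0 * 2 ** np.arange(n_standard_dilutions)
    std_od = _sigmoid_od(std_dil, 1.0)
    if noise_sd > 0:
        std_od = np.clip(std_od + rng.normal(0, noise_sd, std_od.size), 0, None)
    standard = StandardCurve(
        series=DilutionSeries("standard", list(std_dil), list(std_od)),
        anchor_dilution=200.0,
        anchor_units=100.0,
    )
    samples: dict[str, DilutionSeries] = {}
    sample_dil = 100.0 * 2 ** np.arange(n_sample_dilutions)
    for sample_id in sorted(true_titers):
        od = _sigmoid_od(sample_dil, true_titers[sample_id])
        if noise_sd > 0:
            od = np.clip(od + rng.normal(0, noise_sd, od.size), 0, None)
        samples[sample_id] = DilutionSeries(sample_id, list(sample_dil), list(od))
    return samples, standard


def simulate_ct(
    true_folds: dict[str, float], seed: int, calibrator_ct: tuple[float, float] = (22.0, 18.0), noise_sd: float = 0.0
) -> tuple[dict[str, CtTable], CtTable]:
    """Synthetic qPCR Ct tables with known fold changes vs a calibrator."""
    rng = np.random.default_rng(seed)
    cal = CtTable("calibrator", *calibrator_ct)
    out: dict[str, CtTable] = {}
    for sample_id in sorted(true_folds):
        fold = true_folds[sample_id]
        if fold <= 0:
            raise ValueError("fold changes must be positive")
        dct = cal.delta_ct - np.log2(fold)
        ct_ref = cal.ct_ref + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0)
        out[sample_id] = CtTable(sample_id, ct_ref + dct, ct_ref)
    return out, cal
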