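"""Uracil-density and codon-bias statistics on coding sequences.

The uracil density of a gene is the count of T bases over its length (T in
DNA reads as U in the transcript).  The codon-bias table reports, for each
hydrophobic amino acid, the relative usage of its synonymous codons pooled
over a gene set, flagging the codon(s) of maximal uracil content.  Gene
classes (membrane vs cytoplasmic) are compared with a Welch two-sample test
on their density distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from scipy import stats

from .errors import DegenerateDataError, ParameterError

__all__ = [
    "SequenceRecord",
    "CodonBiasTable",
    "HYDROPHOBIC_AA",
    "uracil_density",
    "codon_bias",
    "compare_classes",
    "load_records",
    "generate_records",
]

HYDROPHOBIC_AA = ("A", "V", "L", "I", "F", "M", "W")
GENE_CLASSES = ("membrane", "cytoplasmic", "unassigned")
_VALID = set("ACGT")


@dataclass(frozen=True)
class SequenceRecord:
    gene_id: str
    sequence: str
    gene_class: str = "unassigned"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ParameterError(f"{self.gene_id}: empty sequence")
        if self.gene_class not in GENE_CLASSES:
            raise ParameterError(f"{self.gene_id}: unknown class {self.gene_class!r}")


def _check_alphabet(gene_id: str, seq: str) -> None:
    bad = [i for i, ch in enumerate(seq) if ch not in _VALID]
    if bad:
        shown = ", ".join(str(i) for i in bad[:10])
        more = f" (+{len(bad) - 10} more)" if len(bad) > 10 else ""
        raise ParameterError(
            f"{gene_id}: non-canonical bases at positions {shown}{more}"
        )


def uracil_density(record: SequenceRecord | str) -> float:
    """T count divided by sequence length (the U density of the transcript)."""
    if isinstance(record, SequenceRecord):
        gene_id, seq = record.gene_id, record.sequence.upper()
    else:
        gene_id, seq = "<seq>", record.upper()
    if not seq:
        raise ParameterError("empty sequence")
    _check_alphabet(gene_id, seq)
    return seq.count("T") / len(seq)


@dataclass
class CodonBiasTable:
    """Per-amino-acid synonymous codon usage.

    ``table`` columns: amino_acid, codon, count, fraction, max_u (bool);
    fractions sum to 1 within each amino acid (NaN-filled when an amino acid
    was never observed).
    """

    table: pd.DataFrame
    n_codons_counted: int
    n_internal_stops: int


def codon_bias(
    records: list[SequenceRecord],
    amino_acids: tuple[str, ...] = HYDROPHOBIC_AA,
    table_id: int = 1,
) -> CodonBiasTable:
    """Pooled relative codon usage for the given amino acids.

    Sequences must have length divisible by 3.  Internal stop codons are
    counted and excluded from usage totals; a terminal stop is ignored.
    Ties for highest uracil content are all flagged.
    """
    code = CodonTable.unambiguous_dna_by_id[table_id]
    aa_to_codons: dict[str, list[str]] = {}
    for codon, aa in code.forward_table.items():
        aa_to_codons.setdefault(aa, []).append(codon)
    for aa in amino_acids:
        if aa not in aa_to_codons:
            raise ParameterError(f"no codons for amino acid {aa!r} in table {table_id}")

    counts: dict[str, int] = {}
    n_internal_stops = 0
    n_counted = 0
    for rec in records:
        seq = rec.sequence.upper()
        _check_alphabet(rec.gene_id, seq)
        if len(seq) % 3:
            raise ParameterError(f"{rec.gene_id}: length {len(seq)} not divisible by 3")
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        for pos, codon in enumerate(codons):
            if codon in code.stop_codons:
                if pos != len(codons) - 1:
                    n_internal_stops += 1
                continue
            counts[codon] = counts.get(codon, 0) + 1
            n_counted += 1

    rows = []
    for aa in amino_acids:
        fam = sorted(aa_to_codons[aa])
        fam_counts = np.array([counts.get(c, 0) for c in fam], dtype=float)
        total = fam_counts.sum()
        fractions = fam_counts / total if total > 0 else np.full(len(fam), np.nan)
        u_content = np.array([c.count("T") for c in fam])
        max_u = u_content == u_content.max()
        for c, n, f, m in zip(fam, fam_counts, fractions, max_u):
            rows.append(dict(amino_acid=aa, codon=c, count=int(n), fraction=f, max_u=bool(m)))
    return CodonBiasTable(pd.DataFrame(rows), n_counted, n_internal_stops)


def compare_classes(records: list[SequenceRecord]) -> dict:
    """Welch two-sample comparison of membrane vs cytoplasmic uracil densities.

    Returns per-class summaries (n, median, q1, q3, mean) plus the t statistic
    and p-value.  Raises if a class is empty or both are zero-variance.
    """
    dens = {"membrane": [], "cytoplasmic": []}
    for rec in records:
        if rec.gene_class in dens:
            dens[rec.gene_class].append(uracil_density(rec))
    for cls, vals in dens.items():
        if len(vals) < 2:
            raise ParameterError(f"class {cls!r} needs >= 2 records (got {len(vals)})")
    mem = np.asarray(dens["membrane"])
    cyt = np.asarray(dens["cytoplasmic"])
    if np.ptp(mem) == 0 and np.ptp(cyt) == 0:
        raise DegenerateDataError("zero variance in both classes; test undefined")
    t, p = stats.ttest_ind(mem, cyt, equal_var=False)
    summary = {}
    for cls, vals in (("membrane", mem), ("cytoplasmic", cyt)):
        summary[cls] = dict(
            n=len(vals),
            median=float(np.median(vals)),
            q1=float(np.quantile(vals, 0.25)),
            q3=float(np.quantile(vals, 0.75)),
            mean=float(vals.mean()),
        )
    return dict(classes=summary, t_statistic=float(t), p_value=float(p))


def load_records(fasta_path, classes_csv=None) -> list[SequenceRecord]:
    """Read CDSs from FASTA, optionally joining a (gene_id, class) CSV."""
    classes = {}
    if classes_csv is not None:
        df = pd.read_csv(classes_csv)
        classes = dict(zip(df["gene_id"].astype(str), df["class"].astype(str)))
    records = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        records.append(
            SequenceRecord(rec.id, str(rec.seq).upper(), classes.get(rec.id, "unassigned"))
        )
    if not records:
        raise ParameterError(f"no sequences found in {fasta_path}")
    return records


def generate_records(
    n_per_class: int = 50,
    n_codons: int = 200,
    membrane_t_bias: float = 1.6,
    seed: int = 0,
) -> list[SequenceRecord]:
    """Synthetic two-class CDS set with a controllable T enrichment.

    Membrane-class genes draw codons with T-containing codons upweighted by
    ``membrane_t_bias``; cytoplasmic genes draw uniformly.  Start codon ATG,
    terminal stop TAA, no internal stops.
    """
    rng = np.random.default_rng(seed)
    code = CodonTable.unambiguous_dna_by_id[1]
    sense = sorted(code.forward_table)
    t_weight = np.array([membrane_t_bias ** c.count("T") for c in sense])
    records = []
    for cls, weights in (("membrane", t_weight), ("cytoplasmic", np.ones(len(sense)))):
        p = weights / weights.sum()
        for k in range(n_per_class):
            body = rng.choice(sense, size=n_codons - 2, p=p)
            seq = "ATG" + "".join(body) + "TAA"
            records.append(SequenceRecord(f"{cls}_{k:03d}", seq, cls))
    return records
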