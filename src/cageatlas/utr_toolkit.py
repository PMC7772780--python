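"""5'UTR leader reconstruction and translatability metrics.

Alternate promoters can swap in different transcript leaders, and a
leader's length, GC content, and upstream open reading frames (uORFs)
together set how efficiently the main ORF is translated.  This module
rebuilds spliced leaders from transcript models, censuses uORFs (every
ATG whose A lies in the leader, translated in frame to the first stop,
which may fall downstream of the leader), finds the longest forward-frame
ORF of a sequence, and checks splice junctions against the canonical
GT/AG rule.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .io_formats import TranscriptModel

STOP_CODONS = {"TAA", "TAG", "TGA"}
IUPAC_OK = set("ACGTN")


@dataclass(frozen=True)
class ORFRecord:
    start_offset: int  # 0-based offset of the A of the ATG in the query
    aa_length: int  # peptide length in amino acids, stop excluded
    has_stop: bool

    @property
    def nt_length(self) -> int:
        """Nucleotide length including the stop codon (when present)."""
        return 3 * self.aa_length + (3 if self.has_stop else 0)


@dataclass(frozen=True)
class SpliceJunction:
    intron_id: str
    donor_seq: str  # first intronic bases at the 5' splice site
    acceptor_seq: str  # last intronic bases at the 3' splice site


@dataclass
class UTRReport:
    transcript_id: str
    leader_seq: str
    length_bp: int
    gc: float | None = None
    uorfs: list[ORFRecord] | None = None

    @property
    def n_uorfs(self) -> int:
        """uORF count; only ORFs that reach an in-frame stop are counted."""
        return sum(1 for o in self.uorfs or [] if o.has_stop)


def _check_alphabet(seq: str, allow_n: bool = True) -> str:
    seq = seq.upper()
    allowed = IUPAC_OK if allow_n else IUPAC_OK - {"N"}
    bad = set(seq) - allowed
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return seq


def gc_content(seq: str) -> float:
    """Fraction (G+C) / (A+C+G+T); N bases are excluded from the count."""
    seq = _check_alphabet(seq)
    if not seq:
        raise ValueError("empty sequence")
    counts = {b: seq.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise ValueError("sequence has no unambiguous bases")
    return (counts["G"] + counts["C"]) / denom


def extract_transcript_seq(tx: TranscriptModel, genome) -> str:
    """Spliced transcript sequence in 5'->3' orientation.

    ``genome`` is any mapping chrom -> indexable sequence (pyfaidx.Fasta,
    dict of strings, ...).  Minus-strand exons are reverse-complemented.
    """
    chrom_seq = genome[tx.chrom]
    chrom_len = len(chrom_seq)
    parts = []
    for s, e in tx.exons:
        if s < 0 or e > chrom_len:
            raise ValueError(
                f"exon [{s},{e}) of {tx.transcript_id} outside {tx.chrom} (len {chrom_len})"
            )
        piece = str(chrom_seq[s:e]).upper()
        if tx.strand == "-":
            piece = str(Seq(piece).reverse_complement())
        parts.append(piece)
    return "".join(parts)


def reconstruct_5utr(tx: TranscriptModel, genome) -> UTRReport:
    """Spliced 5'UTR leader: transcript sequence truncated at the CDS start."""
    if tx.cds_start is None:
        raise ValueError(f"{tx.transcript_id} is non-coding: no CDS start")
    leader = extract_transcript_seq(tx, genome)[: tx.cds_start]
    return UTRReport(
        transcript_id=tx.transcript_id, leader_seq=leader, length_bp=len(leader)
    )


def find_uorfs(leader_seq: str, downstream_seq: str = "") -> list[ORFRecord]:
    """All upstream ORFs initiating at an ATG within the leader.

    Translation runs in frame through leader + downstream sequence to the
    first stop codon.  ORFs that never reach a stop are reported with
    has_stop = False.  Overlapping and nested uORFs are all returned,
    ordered by start offset.
    """
    leader = _check_alphabet(leader_seq, allow_n=False)
    full = leader + _check_alphabet(downstream_seq, allow_n=False)
    out = []
    for i in range(len(leader)):
        if full[i : i + 3] != "ATG":
            continue
        aa = 0
        has_stop = False
        for j in range(i, len(full) - 2, 3):
            codon = full[j : j + 3]
            if codon in STOP_CODONS:
                has_stop = True
                break
            aa += 1
        out.append(ORFRecord(start_offset=i, aa_length=aa, has_stop=has_stop))
    return out


def longest_orf(seq: str) -> ORFRecord | None:
    """Longest complete ORF (ATG..stop) across the three forward frames.

    Length ties go to the most 5' start.  Returned aa_length excludes the
    stop; the conventional "ORF length" in nucleotides including the stop
    is ``3 * aa_length + 3`` (see :attr:`ORFRecord.nt_length`).
    """
    seq = _check_alphabet(seq, allow_n=False)
    best: ORFRecord | None = None
    for i in range(len(seq) - 2):
        if seq[i : i + 3] != "ATG":
            continue
        for j in range(i, len(seq) - 2, 3):
            if seq[j : j + 3] in STOP_CODONS:
                cand = ORFRecord(start_offset=i, aa_length=(j - i) // 3, has_stop=True)
                if best is None or cand.nt_length > best.nt_length:
                    best = cand
                break
    return best


def check_canonical_junction(junction: SpliceJunction) -> bool:
    """True iff the intron starts with GT and ends with AG."""
    donor = _check_alphabet(junction.donor_seq)
    acceptor = _check_alphabet(junction.acceptor_seq)
    if len(donor) < 2 or len(acceptor) < 2:
        raise ValueError(
            f"junction {junction.intron_id}: donor/acceptor shorter than 2 nt"
        )
    return donor.startswith("GT") and acceptor.endswith("AG")


def transcript_junctions(tx: TranscriptModel, genome, donor_len: int = 10, acceptor_len: int = 15) -> list[SpliceJunction]:
    """Donor/acceptor intronic sequences for each intron of a transcript."""
    chrom_seq = genome[tx.chrom]
    out = []
    for k, (s, e) in enumerate(tx.introns(), start=1):
        intron = str(chrom_seq[s:e]).upper()
        if tx.strand == "-":
            intron = str(Seq(intron).reverse_complement())
        out.append(
            SpliceJunction(
                intron_id=f"{tx.transcript_id}.intron{k}",
                donor_seq=intron[:donor_len],
                acceptor_seq=intron[-acceptor_len:],
            )
        )
    return out


def utr_report(tx: TranscriptModel, genome) -> UTRReport:
    """Leader + GC + uORF census for a coding transcript (Table-style row)."""
    rep = reconstruct_5utr(tx, genome)
    full = extract_transcript_seq(tx, genome)
    rep.gc = gc_content(rep.leader_seq) if rep.leader_seq else None
    rep.uorfs = find_uorfs(rep.leader_seq, full[tx.cds_start :])
    return rep
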