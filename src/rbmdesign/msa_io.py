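"""Alignment and label I/O, sequence/PAM encoding, weighting and splits.

Protein sequences are handled as rows of integer codes over a 21-letter
alphabet (20 amino acids + gap, gap last).  PAM recognition motifs are
encoded as binary accepted/mask matrices over the four nucleotides in the
fixed column order (A, T, C, G), so that a 5-position motif flattens to a
20-component vector.  Cluster-based sequence weights (1/|cluster|) and
cluster-disjoint train/validation splits follow the standard reweighting
protocol for protein-family models.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: canonical protein alphabet: 20 amino acids then the gap symbol (code q-1 = 20)
PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY-"
GAP = "-"

#: residue characters mapped to gap under the default ambiguity policy
AMBIGUOUS_RESIDUES = set("XBZJUO")

#: nucleotide column order used for PAM label vectors
NT_ORDER = "ATCG"

IUPAC_NT = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
#: accepted-nucleotide set (frozenset) -> IUPAC code, for decoding predictions
IUPAC_FROM_SET = {frozenset(v): k for k, v in IUPAC_NT.items() if k != "U"}


class AlignmentFormatError(ValueError):
    """Raised on ragged records, unknown characters or malformed label rows."""


@dataclass
class Alignment:
    """A weighted, integer-encoded multiple sequence alignment.

    rows[s, i] is the symbol code of sequence s at column i; codes index into
    ``alphabet``.  ``weights`` are per-sequence positive reals (uniform 1.0
    until :func:`compute_cluster_weights` is applied); ``cluster_id`` is None
    until clustering is computed or imported.
    """

    ids: list[str]
    rows: np.ndarray
    alphabet: str = PROTEIN_ALPHABET
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]
    cluster_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.int64)
        if self.rows.ndim != 2:
            raise ValueError("rows must be a 2-D (n_sequences x L) array")
        if len(self.ids) != self.rows.shape[0]:
            raise ValueError("ids and rows disagree on the number of sequences")
        if self.rows.size and (self.rows.min() < 0 or self.rows.max() >= self.q):
            raise ValueError("symbol codes out of range for the alphabet")
        if self.weights is None:
            self.weights = np.ones(self.rows.shape[0])
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights <= 0):
            raise ValueError("weights must be positive")

    @property
    def n(self) -> int:
        return self.rows.shape[0]

    @property
    def L(self) -> int:
        return self.rows.shape[1]

    @property
    def q(self) -> int:
        return len(self.alphabet)

    def sequence(self, s: int) -> str:
        return decode_sequence(self.rows[s], self.alphabet)

    def subset(self, idx: np.ndarray) -> "Alignment":
        idx = np.asarray(idx)
        return Alignment(
            ids=[self.ids[i] for i in idx],
            rows=self.rows[idx],
            alphabet=self.alphabet,
            weights=self.weights[idx],
            cluster_id=None if self.cluster_id is None else self.cluster_id[idx],
        )


def encode_sequence(seq: str, alphabet: str = PROTEIN_ALPHABET,
                    on_ambiguous: str = "gap") -> np.ndarray:
    """Encode one aligned sequence to integer codes.

    '.' and '-' both map to the gap code; lowercase is uppercased.  Ambiguous
    residues (X, B, Z, J, U, O) map to gap with a logged warning, or raise if
    ``on_ambiguous == "error"``.
    """
    lookup = {c: i for i, c in enumerate(alphabet)}
    gap_code = lookup.get(GAP)
    codes = np.empty(len(seq), dtype=np.int64)
    for pos, ch in enumerate(seq):
        c = ch.upper()
        if c == ".":
            c = GAP
        if c in lookup:
            codes[pos] = lookup[c]
        elif c in AMBIGUOUS_RESIDUES and gap_code is not None:
            if on_ambiguous == "error":
                raise AlignmentFormatError(
                    f"ambiguous residue {c!r} at position {pos}")
            logger.warning("ambiguous residue %r at position %d mapped to gap",
                           c, pos)
            codes[pos] = gap_code
        else:
            raise AlignmentFormatError(
                f"unknown character {ch!r} at position {pos}")
    return codes


def decode_sequence(codes: np.ndarray, alphabet: str = PROTEIN_ALPHABET) -> str:
    return "".join(alphabet[c] for c in np.asarray(codes))


def read_alignment(path, format: str = "fasta", alphabet: str = PROTEIN_ALPHABET,
                   on_ambiguous: str = "gap") -> Alignment:
    """Read an aligned FASTA or Stockholm file into an :class:`Alignment`.

    All records must have equal length; a ragged record raises
    :class:`AlignmentFormatError` naming it.  Weights are uniform 1.0 and
    clusters unset.
    """
    if format == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
    elif format == "stockholm":
        records = list(AlignIO.read(str(path), "stockholm"))
    else:
        raise ValueError(f"unsupported alignment format {format!r}")
    if not records:
        raise AlignmentFormatError(f"no records found in {path}")
    L = len(records[0].seq)
    ids, rows = [], []
    for rec in records:
        if len(rec.seq) != L:
            raise AlignmentFormatError(
                f"record {rec.id!r} has length {len(rec.seq)}, expected {L}")
        try:
            rows.append(encode_sequence(str(rec.seq), alphabet, on_ambiguous))
        except AlignmentFormatError as exc:
            raise AlignmentFormatError(f"record {rec.id!r}: {exc}") from exc
        ids.append(rec.id)
    return Alignment(ids=ids, rows=np.stack(rows), alphabet=alphabet)


def write_alignment(aln: Alignment, path, format: str = "fasta") -> None:
    records = [
        SeqRecord(Seq(aln.sequence(s)), id=aln.ids[s], description="")
        for s in range(aln.n)
    ]
    if format == "fasta":
        SeqIO.write(records, str(path), "fasta")
    elif format == "stockholm":
        AlignIO.write(AlignIO.MultipleSeqAlignment(records), str(path),
                      "stockholm")
    else:
        raise ValueError(f"unsupported alignment format {format!r}")


def fractional_identity(a: np.ndarray, b: np.ndarray) -> float:
    """Matches / aligned length, gap counted as an ordinary 21st symbol."""
    return float(np.mean(a == b))


def compute_cluster_weights(aln: Alignment, threshold: float = 0.9,
                            clusters: dict[str, int] | None = None) -> Alignment:
    """Cluster sequences and set weights to 1/|cluster|.

    Internal clustering is greedy incremental single-linkage-to-representative:
    the first sequence seeds cluster 0; each subsequent sequence joins the
    first cluster whose representative is >= ``threshold`` fractional identity
    to it, else seeds a new cluster.  An externally computed mapping
    (seq_id -> cluster index, e.g. from MMseqs2) may be supplied instead via
    ``clusters``.  After this call sum(weights) equals the number of clusters.
    """
    if aln.n == 0:
        raise ValueError("cannot cluster an empty alignment")
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    if clusters is not None:
        missing = [i for i in aln.ids if i not in clusters]
        if missing:
            raise ValueError(f"external clustering misses ids: {missing[:5]}")
        cluster_id = np.array([clusters[i] for i in aln.ids], dtype=np.int64)
    else:
        rep_rows = np.empty_like(aln.rows)
        n_reps = 0
        cluster_id = np.empty(aln.n, dtype=np.int64)
        for s in range(aln.n):
            row = aln.rows[s]
            if n_reps:
                ident = (rep_rows[:n_reps] == row).mean(axis=1)
                hits = np.flatnonzero(ident >= threshold)
            else:
                hits = np.empty(0, dtype=int)
            if hits.size:
                cluster_id[s] = hits[0]  # first qualifying representative
            else:
                cluster_id[s] = n_reps
                rep_rows[n_reps] = row
                n_reps += 1
    _, inverse, counts = np.unique(cluster_id, return_inverse=True,
                                   return_counts=True)
    weights = 1.0 / counts[inverse]
    return replace(aln, weights=weights, cluster_id=cluster_id)


@dataclass
class SplitSpec:
    """Cluster-disjoint validation split specification."""

    validation_fraction: float = 0.10
    similarity_threshold: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.validation_fraction < 1.0):
            raise ValueError("validation_fraction must be in (0, 1)")


def split_train_validation(aln: Alignment, spec: SplitSpec) -> tuple[Alignment, Alignment]:
    """Split whole clusters into train/validation partitions.

    Clusters are visited in seeded random order; a cluster is added to the
    validation side only while it does not overshoot the target sequence
    count, so the validation side holds the closest achievable fraction
    >= ``validation_fraction``.  If every remaining cluster overshoots, the
    smallest one is added with a warning (smallest superset).
    """
    if aln.cluster_id is None:
        aln = compute_cluster_weights(aln, spec.similarity_threshold)
    rng = np.random.default_rng(spec.seed)
    cids = np.unique(aln.cluster_id)
    order = rng.permutation(cids)
    sizes = {c: int(np.sum(aln.cluster_id == c)) for c in cids}
    target = int(np.ceil(spec.validation_fraction * aln.n))
    chosen: list[int] = []
    n_val = 0
    for c in order:
        if n_val >= target:
            break
        if n_val + sizes[c] <= target:
            chosen.append(int(c))
            n_val += sizes[c]
    if n_val < target:
        remaining = [c for c in order if int(c) not in chosen]
        if remaining:
            smallest = min(remaining, key=lambda c: sizes[c])
            warnings.warn(
                "validation fraction unreachable with whole clusters; "
                "returning smallest superset", stacklevel=2)
            chosen.append(int(smallest))
            n_val += sizes[smallest]
    val_mask = np.isin(aln.cluster_id, chosen)
    return aln.subset(np.flatnonzero(~val_mask)), aln.subset(np.flatnonzero(val_mask))


# ---------------------------------------------------------------------------
# PAM labels
# ---------------------------------------------------------------------------

@dataclass
class PamLabel:
    """Accepted-nucleotide matrix for the first n positions of a PAM motif.

    accepted[k, b] = 1 iff nucleotide NT_ORDER[b] is compatible with the motif
    at position k; mask[k, b] = 1 iff that unit was observed.  accepted is 0
    wherever mask is 0.
    """

    seq_id: str
    accepted: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.accepted = np.asarray(self.accepted, dtype=np.int8)
        self.mask = np.asarray(self.mask, dtype=np.int8)
        if self.accepted.shape != self.mask.shape or self.accepted.ndim != 2 \
                or self.accepted.shape[1] != 4:
            raise ValueError("accepted and mask must both be (n_positions, 4)")
        if np.any(self.accepted[self.mask == 0] != 0):
            raise ValueError("accepted must be 0 wherever mask is 0")

    @property
    def n_positions(self) -> int:
        return self.accepted.shape[0]

    def flat(self) -> np.ndarray:
        return self.accepted.ravel()


def encode_pam_motif(motif: str, n_positions: int = 5,
                     seq_id: str = "") -> PamLabel:
    """Encode an IUPAC nucleotide motif as a PamLabel.

    Columns are ordered (A, T, C, G).  Only the first ``n_positions``
    characters are encoded; if the motif is shorter, the missing tail is
    masked out (mask 0, accepted 0).  Besides the IUPAC codes, '-' denotes an
    observed position at which no nucleotide is accepted (the empty set has
    no IUPAC code), so any binary acceptance matrix round-trips through its
    motif string.
    """
    accepted = np.zeros((n_positions, 4), dtype=np.int8)
    mask = np.zeros((n_positions, 4), dtype=np.int8)
    for k in range(min(n_positions, len(motif))):
        code = motif[k].upper()
        if code == "-":
            mask[k, :] = 1
            continue
        if code not in IUPAC_NT:
            raise AlignmentFormatError(
                f"unknown IUPAC nucleotide code {motif[k]!r} at position {k}")
        mask[k, :] = 1
        for b, nt in enumerate(NT_ORDER):
            if nt in IUPAC_NT[code]:
                accepted[k, b] = 1
    return PamLabel(seq_id=seq_id, accepted=accepted, mask=mask)


def pam_matrix_to_motif(accepted: np.ndarray) -> str:
    """Map an accepted-nucleotide binary matrix back to an IUPAC string.

    An empty accepted set at a position (nothing predicted accepted) is
    rendered as '-', the inverse of :func:`encode_pam_motif`'s convention.
    """
    out = []
    for row in np.asarray(accepted):
        nts = frozenset(NT_ORDER[b] for b in range(4) if row[b])
        out.append(IUPAC_FROM_SET.get(nts, "-") if nts else "-")
    return "".join(out)


def read_pam_labels(path, alignment: Alignment | None = None,
                    n_positions: int = 5) -> list[PamLabel]:
    """Read a TSV of ``seq_id<TAB>motif`` rows into PamLabels.

    Rows whose id is absent from ``alignment`` (when given) are reported with
    a warning and dropped.  Malformed rows raise with their line number.
    """
    known = set(alignment.ids) if alignment is not None else None
    labels: list[PamLabel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise AlignmentFormatError(
                    f"{path}: malformed label row at line {lineno}: {line!r}")
            seq_id, motif = parts
            if known is not None and seq_id not in known:
                warnings.warn(
                    f"label row {lineno}: id {seq_id!r} absent from the "
                    "alignment; dropped", stacklevel=2)
                continue
            try:
                labels.append(encode_pam_motif(motif, n_positions, seq_id))
            except AlignmentFormatError as exc:
                raise AlignmentFormatError(
                    f"{path}: line {lineno}: {exc}") from exc
    return labels


def write_pam_labels(labels: list[PamLabel], path) -> None:
    with open(path, "w") as fh:
        for lab in labels:
            obs = int(lab.mask[:, 0].sum())
            fh.write(f"{lab.seq_id}\t{pam_matrix_to_motif(lab.accepted[:obs])}\n")


def read_cluster_tsv(path) -> dict[str, int]:
    clusters: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise AlignmentFormatError(
                    f"{path}: malformed cluster row at line {lineno}")
            clusters[parts[0]] = int(parts[1])
    return clusters


def write_cluster_tsv(aln: Alignment, path) -> None:
    if aln.cluster_id is None:
        raise ValueError("alignment has no clusters to write")
    with open(path, "w") as fh:
        for i, c in zip(aln.ids, aln.cluster_id):
            fh.write(f"{i}\t{int(c)}\n")


def hamming_distance(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column count at which two encoded sequences differ (gap = symbol).

    Broadcasts over leading batch dimensions.
    """
    return np.asarray(np.sum(np.asarray(a) != np.asarray(b), axis=-1))
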