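"""Small sequence-arithmetic helpers."""

from .errors import SequenceError

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: Ambiguity / non-standard one-letter codes tolerated in input proteins.
AMBIGUOUS_AA = frozenset("BJZXUO")


def encoded_protein_length(cdna_nt: int) -> int:
    """Number of residues encoded by a full-length ORF of ``cdna_nt`` nucleotides.

    The ORF is taken to include its stop codon, so a 966-nt coding sequence
    encodes 966/3 - 1 = 321 residues.
    """
    if cdna_nt < 6:
        raise SequenceError(f"ORF of {cdna_nt} nt is too short to encode a protein")
    if cdna_nt % 3:
        raise SequenceError(f"ORF length {cdna_nt} is not a multiple of 3")
    return cdna_nt // 3 - 1


def validate_protein_sequence(sequence: str) -> None:
    """Raise :class:`SequenceError` at the first character that is not a standard
    residue or a tolerated ambiguity code."""
    allowed = STANDARD_AA | AMBIGUOUS_AA
    for i, ch in enumerate(sequence):
        if ch.upper() not in allowed:
            raise SequenceError(
                f"invalid residue {ch!r} at offset {i}", offset=i
            )
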