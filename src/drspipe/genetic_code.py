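"""Standard genetic code and single-base codon-change consequences.

Used to interpret A-to-I editing sites in coding sequence: inosine is read as
guanosine by the translation machinery, so an edited A behaves as G and may
recode the amino acid. The consequence caller is generic over the edited base
so that any substitution can be classified.
"""

from __future__ import annotations

from dataclasses import dataclass

STOP = "*"

# Standard genetic code, DNA alphabet (T == U).
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": STOP, "TAG": STOP,
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": STOP, "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

# Four-class side-chain property scheme used to flag chemically consequential
# recoding (e.g. Arg -> Gly crosses charge classes).
AA_PROPERTY = {
    **{aa: "nonpolar" for aa in "AVLIPMFWG"},
    **{aa: "polar-uncharged" for aa in "STCYNQ"},
    **{aa: "positively-charged" for aa in "KRH"},
    **{aa: "negatively-charged" for aa in "DE"},
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    codon = codon.upper().replace("U", "T")
    try:
        return CODON_TABLE[codon]
    except KeyError:
        raise ValueError(f"invalid codon {codon!r}") from None


@dataclass(frozen=True)
class CodonChange:
    category: str  # synonymous | missense | stop_gained | stop_lost | stop_retained
    aa_before: str
    aa_after: str
    property_change: bool


def codon_consequence(
    codon: str,
    edit_offset: int,
    edited_base: str,
    expected_ref: str | None = None,
) -> CodonChange:
    """Consequence of substituting ``edited_base`` at ``edit_offset`` of ``codon``.

    Parameters
    ----------
    codon : three-letter codon on the coding strand (T and U equivalent).
    edit_offset : 0, 1 or 2, position within the codon.
    edited_base : the base read after modification (G for A-to-I).
    expected_ref : when given, the reference base that must sit at the offset;
        a mismatch raises ``ValueError`` signalling an inconsistent site call.

    ``property_change`` is True only when both codons encode amino acids and
    their side-chain property classes differ.
    """
    codon = codon.upper().replace("U", "T")
    edited_base = edited_base.upper().replace("U", "T")
    if len(codon) != 3 or any(b not in "ACGT" for b in codon):
        raise ValueError(f"invalid codon {codon!r}")
    if not 0 <= edit_offset <= 2:
        raise ValueError(f"edit_offset must be 0..2, got {edit_offset}")
    if edited_base not in "ACGT":
        raise ValueError(f"invalid edited base {edited_base!r}")
    if expected_ref is not None and codon[edit_offset] != expected_ref.upper():
        raise ValueError(
            f"reference base at codon offset {edit_offset} is "
            f"{codon[edit_offset]!r}, expected {expected_ref!r}: inconsistent site call"
        )
    after_codon = codon[:edit_offset] + edited_base + codon[edit_offset + 1 :]
    aa_before = CODON_TABLE[codon]
    aa_after = CODON_TABLE[after_codon]
    if aa_before == STOP and aa_after == STOP:
        category = "stop_retained"
    elif aa_before == STOP:
        category = "stop_lost"
    elif aa_after == STOP:
        category = "stop_gained"
    elif aa_before == aa_after:
        category = "synonymous"
    else:
        category = "missense"
    property_change = (
        aa_before != STOP
        and aa_after != STOP
        and AA_PROPERTY[aa_before] != AA_PROPERTY[aa_after]
    )
    return CodonChange(category, aa_before, aa_after, property_change)
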