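"""Lexical validation of Swiss-Prot style protein accessions.

Kept in a private helper module so both the table loaders and the resolver
can share it without an import cycle.
"""

import re

# Classic accession: six characters, first alphabetic, all uppercase
# alphanumeric, no spaces or punctuation.
_ACCESSION6_RE = re.compile(r"^[A-Z][A-Z0-9]{5}$")
# Extended form: ten characters with the same character class, as used for
# accessions issued after the classic six-character space filled up.
_ACCESSION10_RE = re.compile(r"^[A-Z][A-Z0-9]{9}$")


def is_valid_accession(candidate: str, extended: bool = False) -> bool:
    """True iff *candidate* is lexically a valid protein accession.

    Lowercase input is rejected rather than case-folded: accessions are a
    strict identifier vocabulary, and silently accepting near-misses is the
    exact failure mode this toolkit audits for.
    """
    if not isinstance(candidate, str):
        return False
    if _ACCESSION6_RE.match(candidate):
        return True
    if extended and _ACCESSION10_RE.match(candidate):
        return True
    return False
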