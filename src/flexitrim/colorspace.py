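"""SOLiD 2-base (dibase) color-space encoding and decoding.

SOLiD sequencers interrogate overlapping base pairs: each color digit
encodes the transition between two adjacent bases, so a read is stored as
one known primer base followed by ``len - 1`` color digits.  The
transition matrix has the usual properties: identical adjacent bases give
color 0, the mapping is symmetric (XY and YX give the same color), and
each row is a permutation of {0,1,2,3}.  Knowing one base and a color
therefore determines the next base, which is what makes decoding from the
primer base possible.
"""

from __future__ import annotations

from .errors import ConfigError, EncodingError

_BASES = "ACGT"

#: Dibase transition matrix: (base, base) -> color digit.
TRANSITIONS: dict[tuple[str, str], str] = {}
for _i, _a in enumerate(_BASES):
    for _j, _b in enumerate(_BASES):
        TRANSITIONS[(_a, _b)] = str(_i ^ _j)

#: Inverse mapping: (base, color digit) -> next base.
_NEXT_BASE: dict[tuple[str, str], str] = {
    (a, c): b for (a, b), c in TRANSITIONS.items()
}


def encode(letters: str) -> str:
    """Encode a letter-space sequence as primer base + color digits.

    ``encode("AAAA") == "A000"``; a single base encodes to itself with
    zero colors.  Uncalled bases cannot be color-encoded.
    """
    if not letters:
        raise EncodingError("cannot encode an empty sequence")
    letters = letters.upper()
    for ch in letters:
        if ch not in _BASES:
            raise EncodingError(f"cannot color-encode base {ch!r}")
    colors = [TRANSITIONS[(a, b)] for a, b in zip(letters, letters[1:])]
    return letters[0] + "".join(colors)


def decode(colors: str) -> str:
    """Decode primer base + color digits back to letter space.

    Inverse of :func:`encode`.  An uncalled color ``.`` breaks the
    transition chain and raises :class:`EncodingError`.
    """
    if not colors:
        raise EncodingError("cannot decode an empty sequence")
    primer, digits = colors[0].upper(), colors[1:]
    if primer not in _BASES:
        raise EncodingError(f"invalid primer base {primer!r}")
    out = [primer]
    for d in digits:
        if d == ".":
            raise EncodingError("uncalled color '.' cannot be decoded")
        if d not in "0123":
            raise EncodingError(f"invalid color digit {d!r}")
        out.append(_NEXT_BASE[(out[-1], d)])
    return "".join(out)


def tag_to_colorspace(letters: str) -> str:
    """Convert a letter-space tag to its color digits, without primer.

    Matching color reads against a tag uses colors only, so the result is
    primer-independent.  A tag of length m yields m-1 colors; tags shorter
    than 2 letters carry no transition and are rejected.
    """
    if len(letters) < 2:
        raise ConfigError(
            "a color-space tag needs at least 2 letters (no color derivable "
            f"from {letters!r})"
        )
    return encode(letters)[1:]
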