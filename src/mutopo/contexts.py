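"""Stranded trinucleotide mutation-type catalog.

Single-base substitutions are indexed over 192 stranded categories:
6 pyrimidine-centered substitution classes (C>A, C>G, C>T, T>A, T>C, T>G)
x 16 flanking-base combinations x 2 strand orientations.  Orientation 0
means the reference strand carries the pyrimidine at the mutated site;
orientation 1 means the reference carries the purine and the category is
read off the reverse complement.  Collapsing orientations yields the
conventional 96-channel spectrum.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
PYRIMIDINES = "CT"

#: substitution classes in fixed order, pyrimidine-centered
SUBSTITUTIONS = [("C", "A"), ("C", "G"), ("C", "T"),
                 ("T", "A"), ("T", "C"), ("T", "G")]
SUB_INDEX = {s: i for i, s in enumerate(SUBSTITUTIONS)}

N_TYPES = 192
N_TYPES_COLLAPSED = 96
N_CONTEXT_GROUPS = 64  # 2 orientations x 2 pyrimidine centers x 16 flanks

# numeric base codes; 4 marks any ambiguous base (N, or soft-mask if excluded)
_CODE = np.full(256, 4, dtype=np.int8)
for _b, _i in BASE_INDEX.items():
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_CODE_HARD = np.full(256, 4, dtype=np.int8)  # lowercase treated as ambiguous
for _b, _i in BASE_INDEX.items():
    _CODE_HARD[ord(_b)] = _i


def encode_sequence(seq: str, count_soft_masked: bool = True) -> np.ndarray:
    """Map a DNA string to integer codes 0..3 (A,C,G,T); 4 for ambiguous."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    table = _CODE if count_soft_masked else _CODE_HARD
    return table[raw]


def type_index(ref: str, alt: str, triplet: str) -> int:
    """Index (0..191) of a substitution given its reference trinucleotide.

    Returns -1 when the context contains an ambiguous base.
    ``triplet`` is the reference-strand trinucleotide centered on the site.
    """
    ref, alt, triplet = ref.upper(), alt.upper(), triplet.upper()
    if len(triplet) != 3 or triplet[1] != ref or ref == alt:
        raise ValueError(f"inconsistent mutation {triplet} {ref}>{alt}")
    if any(b not in BASES for b in triplet) or alt not in BASES:
        return -1
    if ref in PYRIMIDINES:
        orient = 0
        sub = SUB_INDEX[(ref, alt)]
        five, three = triplet[0], triplet[2]
    else:
        orient = 1
        sub = SUB_INDEX[(COMPLEMENT[ref], COMPLEMENT[alt])]
        five, three = COMPLEMENT[triplet[2]], COMPLEMENT[triplet[0]]
    return orient * 96 + sub * 16 + BASE_INDEX[five] * 4 + BASE_INDEX[three]


def type_label(idx: int) -> str:
    """Human-readable label, e.g. ``A[C>T]G+`` (``-`` = reverse orientation)."""
    orient, rem = divmod(idx, 96)
    sub, flank = divmod(rem, 16)
    five, three = divmod(flank, 4)
    ref, alt = SUBSTITUTIONS[sub]
    return f"{BASES[five]}[{ref}>{alt}]{BASES[three]}{'+-'[orient]}"


TYPE_LABELS = [type_label(i) for i in range(N_TYPES)]

#: +1 for reference-pyrimidine orientation, -1 for reverse
ORIENTATION_SIGN = np.where(np.arange(N_TYPES) < 96, 1.0, -1.0)


def collapse_to_96(spectrum: np.ndarray) -> np.ndarray:
    """Sum strand-paired categories along the last axis (192 -> 96)."""
    spectrum = np.asarray(spectrum)
    if spectrum.shape[-1] != N_TYPES:
        raise ValueError("expected a 192-type final axis")
    return spectrum[..., :96] + spectrum[..., 96:]


def strand_swap(spectrum: np.ndarray) -> np.ndarray:
    """Exchange the two orientation blocks of a 192-vector."""
    return np.concatenate([spectrum[..., 96:], spectrum[..., :96]], axis=-1)


def context_groups(codes: np.ndarray) -> np.ndarray:
    """Per-position stranded context-group id (0..63), -1 where ambiguous.

    Group id = orient*32 + center*16 + five*4 + three, with center 0 for C
    and 1 for T after orienting to the pyrimidine strand.  Chromosome-end
    positions (no flank) are ambiguous.  Each group feeds 3 mutation types.
    """
    n = codes.shape[0]
    out = np.full(n, -1, dtype=np.int32)
    if n < 3:
        return out
    c5, c0, c3 = codes[:-2], codes[1:-1], codes[2:]
    ok = (c5 < 4) & (c0 < 4) & (c3 < 4)
    # orientation 0: center C (code 1) or T (code 3)
    pyr = (c0 == 1) | (c0 == 3)
    comp = 3 - c0  # A<->T, C<->G under code arithmetic
    center = np.where(pyr, (c0 == 3).astype(np.int32), (comp == 3).astype(np.int32))
    five = np.where(pyr, c5, 3 - c3)
    three = np.where(pyr, c3, 3 - c5)
    orient = (~pyr).astype(np.int32)
    gid = orient * 32 + center * 16 + five * 4 + three
    out[1:-1] = np.where(ok, gid, -1)
    return out


def _group_to_types() -> np.ndarray:
    table = np.empty((N_CONTEXT_GROUPS, 3), dtype=np.int32)
    for g in range(N_CONTEXT_GROUPS):
        orient, rem = divmod(g, 32)
        center, flank = divmod(rem, 16)
        subs = [i for i, (r, _) in enumerate(SUBSTITUTIONS)
                if r == PYRIMIDINES[center]]
        table[g] = [orient * 96 + s * 16 + flank for s in subs]
    return table


#: (64, 3) map from context group to the 3 mutation types it can host
GROUP_TO_TYPES = _group_to_types()

#: (192,) map from mutation type to its context group
TYPE_TO_GROUP = np.empty(N_TYPES, dtype=np.int32)
for _g in range(N_CONTEXT_GROUPS):
    TYPE_TO_GROUP[GROUP_TO_TYPES[_g]] = _g


def group_counts_to_availability(group_counts: np.ndarray) -> np.ndarray:
    """Expand (…, 64) context-group counts to (…, 192) type availability."""
    group_counts = np.asarray(group_counts)
    avail = np.zeros(group_counts.shape[:-1] + (N_TYPES,), dtype=group_counts.dtype)
    for g in range(N_CONTEXT_GROUPS):
        for t in GROUP_TO_TYPES[g]:
            avail[..., t] = group_counts[..., g]
    return avail


def alt_base(type_idx: int, ref_base: str) -> str:
    """Alternate base (reference strand) produced by mutation type at a site."""
    orient, rem = divmod(type_idx, 96)
    sub = rem // 16
    _, alt = SUBSTITUTIONS[sub]
    if orient == 1:
        alt = COMPLEMENT[alt]
    return alt
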