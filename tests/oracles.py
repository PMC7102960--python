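"""Independent brute-force oracles used only by the tests.

The motif-language membership test below enumerates tract/loop
decompositions recursively, with no regular expressions and no shared code
with the scanner it checks.
"""

from __future__ import annotations

LOOP_CHARS = set("ACT")


def in_query_language(
    text: str,
    tract_minima: tuple[int, ...],
    loop_min: int,
    loop_max: int,
    open_ended: bool = True,
) -> bool:
    """Does the whole string decompose as tract1 loop1 ... tractN?"""

    def rec(pos: int, ti: int) -> bool:
        if ti == len(tract_minima):
            return pos == len(text)
        k = tract_minima[ti]
        while True:
            seg = text[pos:pos + k]
            if len(seg) < k or set(seg) != {"G"}:
                return False
            if ti == len(tract_minima) - 1:
                if rec(pos + k, ti + 1):
                    return True
            else:
                for ln in range(loop_min, loop_max + 1):
                    loop = text[pos + k:pos + k + ln]
                    if len(loop) == ln and set(loop) <= LOOP_CHARS:
                        if rec(pos + k + ln, ti + 1):
                            return True
            if not open_ended:
                return False
            k += 1

    return rec(0, 0)


def brute_force_match_starts(
    seq: str,
    tract_minima: tuple[int, ...],
    loop_min: int,
    loop_max: int,
    open_ended: bool = True,
    strict: bool = False,
) -> set[int]:
    """All start positions with some substring in the query language.

    In strict mode tracts are exact-length and the match may not be
    flanked by G on either side.
    """
    starts = set()
    n = len(seq)
    min_total = sum(tract_minima) + loop_min * (len(tract_minima) - 1)
    for i in range(n):
        if strict and i > 0 and seq[i - 1] == "G":
            continue
        for j in range(i + min_total, n + 1):
            if strict and j < n and seq[j] == "G":
                continue
            if in_query_language(
                seq[i:j], tract_minima, loop_min, loop_max,
                open_ended=not strict and open_ended,
            ):
                starts.add(i)
                break
    return starts
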