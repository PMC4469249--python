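"""Independent brute-force oracles used to check the aligner and tier-1
matcher.  These deliberately share no code or algorithmic structure with
the implementations they verify: the local-alignment oracle maximizes a
memoized global-alignment recursion over every substring pair, and the
tier-1 oracle enumerates every placement with a per-position loop."""

from functools import lru_cache


def sw_bruteforce(a, b, match=5, mismatch=-4, gap_open=-12, gap_extend=-4):
    """Best local alignment score = max over all substring pairs of the
    end-to-end alignment score, plus the empty alignment (0)."""

    @lru_cache(maxsize=None)
    def end_to_end(sa, sb, state):
        if not sa and not sb:
            return 0
        best = None
        if sa and sb:
            s = match if sa[0] == sb[0] else mismatch
            best = s + end_to_end(sa[1:], sb[1:], "M")
        if sa:
            g = gap_extend if state == "D" else gap_open
            v = g + end_to_end(sa[1:], sb, "D")
            best = v if best is None or v > best else best
        if sb:
            g = gap_extend if state == "I" else gap_open
            v = g + end_to_end(sa, sb[1:], "I")
            best = v if best is None or v > best else best
        return best

    best = 0
    for i in range(len(a)):
        for i2 in range(i + 1, len(a) + 1):
            sa = a[i:i2]
            for j in range(len(b)):
                for j2 in range(j + 1, len(b) + 1):
                    score = end_to_end(sa, b[j:j2], "M")
                    if score > best:
                        best = score
    return best


def tier1_bruteforce(read, ref, max5=2, max3=4):
    """Exhaustive placement enumeration for the offset-tolerant exact match."""
    hits = []
    for o5 in range(-max5, max5 + 1):
        o3 = o5 + len(read) - len(ref)
        if abs(o3) > max3:
            continue
        overlap = 0
        ok = True
        for j in range(len(read)):
            i = j + o5
            if 0 <= i < len(ref):
                overlap += 1
                if read[j] != ref[i]:
                    ok = False
                    break
        if ok and overlap > 0:
            hits.append((abs(o5), abs(o3), o5, o3))
    if not hits:
        return (False, None, None)
    hits.sort()
    return (True, hits[0][2], hits[0][3])
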