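"""Straight-line, loop-based transliteration of the anchor/baseline rules.

This is a deliberately unoptimized, independent re-implementation of the
marker coding, anchor cleanup and baseline construction (the stages between
gradient thresholding and baseline subtraction), used only as an oracle:
the production path must agree with it exactly. It shares nothing with the
production code but the rule statements.
"""

from __future__ import annotations


def reference_baseline(s, delta, wavelength_nm, t1=5.0, t2=200.0, t3=40, cosmicthres=None):
    """Return (anchor_positions_1based, baseline_list) for one spectrum."""
    n = len(s)

    # threshold coding (strict comparisons)
    d1 = [0] * n
    for i in range(n):
        if delta[i] > t1:
            d1[i] = 1
        elif delta[i] < -t1:
            d1[i] = -1

    # zeros adjacent to +-1 become 2
    d2 = list(d1)
    for i in range(n):
        if d1[i] == 0:
            left = d1[i - 1] if i - 1 >= 0 else 0
            right = d1[i + 1] if i + 1 < n else 0
            if left != 0 or right != 0:
                d2[i] = 2

    # first difference with 0 prepended, keep only +-2
    d3 = [0] * n
    for i in range(1, n):
        v = d2[i] - d2[i - 1]
        d3[i] = v if v in (2, -2) else 0

    # of consecutive equal markers keep leftmost (+2) / rightmost (-2)
    markers = [(i, d3[i]) for i in range(n) if d3[i] != 0]
    cleaned = []
    for pos, sign in markers:
        if cleaned and cleaned[-1][1] == sign:
            if sign == -2:
                cleaned[-1] = (pos, sign)  # rightmost end wins
            # leftmost onset wins: drop the newcomer
        else:
            cleaned.append((pos, sign))
    markers = cleaned

    # eliminate end->onset pairs closer than t2 in wavenumber, repeatedly
    def wavenumber(ch):
        return 1e7 / wavelength_nm[ch]

    done = False
    while not done:
        done = True
        for k in range(len(markers) - 1):
            (pa, sa), (pb, sb) = markers[k], markers[k + 1]
            if sa == -2 and sb == 2 and abs(wavenumber(pa) - wavenumber(pb)) < t2:
                del markers[k : k + 2]
                done = False
                break

    # a feature truncated at the spectrum start has no onset; drop its end
    while markers and markers[0][1] == -2:
        markers.pop(0)
    # first and last channels are reserved for the terminal anchors
    markers = [(p, sgn) for p, sgn in markers if 0 < p < n - 1]

    anchors = [1] + [p + 1 for p, _ in markers] + [n]

    # filter-onset handling on the first feature pair
    if t3 is not None and len(markers) >= 2:
        a2, a3 = anchors[1], anchors[2]
        if a3 - a2 < t3:
            anchors = [anchors[0]] + anchors[3:]
        else:
            # move the onset to the channel before the band maximum where
            # S is minimal but still above S at the band end
            seg = list(s[a2 - 1 : a3])
            peak = a2 - 1 + seg.index(max(seg))
            best = None
            for i in range(a2 - 1, peak):
                p_i = s[i] - s[a3 - 1]
                if p_i > 0 and (best is None or p_i <= best[1]):
                    best = (i, p_i)
            if best is not None:
                anchors[1] = best[0] + 1

    # cosmic-ray features: drop pairs containing |delta| above the ceiling
    if cosmicthres is not None:
        k = 1
        while k + 1 <= len(anchors) - 1:
            on, end = anchors[k], anchors[k + 1]
            if any(abs(delta[i]) > cosmicthres for i in range(on - 1, end)):
                if end == anchors[-1]:
                    del anchors[k]
                else:
                    del anchors[k : k + 2]
            else:
                k += 2

    # baseline: data on [A(2m-1), A(2m)], straight line on the open
    # interval (A(2m), A(2m+1)); B = S at the anchors themselves
    b = list(s)
    k = 1
    while k + 1 <= len(anchors) - 1:
        on, end = anchors[k], anchors[k + 1]
        lo, hi = on - 1, end - 1
        for i in range(lo + 1, hi):
            b[i] = s[lo] + ((i - lo) / (hi - lo)) * (s[hi] - s[lo])
        k += 2
    return anchors, b
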