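"""Numba inner loops for the forward pedigree simulator."""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def meiose_batch(
    p_ends,
    p_anc,
    p_off,
    mode,
    pind,
    xo_pos,
    xo_off,
    coin,
    length,
    out_ends,
    out_anc,
    out_off,
):
    """Produce one generation of haplotypes on one chromosome.

    ``mode[c] == -1``: haplotype ``c`` is a meiotic recombinant of the two
    haplotypes of parent individual ``pind[c]``, with sorted crossover
    positions ``xo_pos[xo_off[c]:xo_off[c+1]]`` and starting haplotype
    ``coin[c]``.  ``mode[c] >= 0``: emit a single pure tract of that
    ancestry (migrant haplotype).  Adjacent same-ancestry segments are
    merged, so every output haplotype tiles ``[0, length)`` exactly.
    Returns the number of tract records written.
    """
    pos = 0
    out_off[0] = 0
    for c in range(mode.size):
        if mode[c] >= 0:
            out_ends[pos] = length
            out_anc[pos] = mode[c]
            pos += 1
            out_off[c + 1] = pos
            continue
        cur = 2 * pind[c] + coin[c]
        k0 = xo_off[c]
        k1 = xo_off[c + 1]
        seg_start = 0.0
        last_anc = -1
        for k in range(k0, k1 + 1):
            seg_end = xo_pos[k] if k < k1 else length
            if seg_end > seg_start:
                i = p_off[cur]
                while p_ends[i] <= seg_start:
                    i += 1
                while True:
                    e = p_ends[i] if p_ends[i] < seg_end else seg_end
                    a = p_anc[i]
                    if a == last_anc:
                        out_ends[pos - 1] = e
                    else:
                        out_ends[pos] = e
                        out_anc[pos] = a
                        last_anc = a
                        pos += 1
                    if p_ends[i] >= seg_end:
                        break
                    i += 1
            cur ^= 1
            seg_start = seg_end
        out_off[c + 1] = pos
    return pos


@njit(cache=True)
def ancestry_lengths(ends, anc, off, n_pops, out):
    """Accumulate per-haplotype, per-ancestry tract length into ``out``
    (shape ``(n_haps, n_pops)``, added in place)."""
    for h in range(off.size - 1):
        start = 0.0
        for i in range(off[h], off[h + 1]):
            out[h, anc[i]] += ends[i] - start
            start = ends[i]


@njit(cache=True)
def bin_tracts(ends, anc, off, n_pops, edges, counts, full, lmass):
    """Histogram tract lengths per ancestry.

    ``edges`` (Morgans-agnostic; same unit as ends) defines bins
    ``[e0, e1), ..., [e_{B-2}, e_{B-1}), [e_{B-1}, inf)`` -> ``B`` bins where
    ``B = len(edges)``.  Tracts shorter than ``e0`` are dropped.  Haplotypes
    consisting of a single tract are counted into ``full`` (per ancestry)
    instead of the bins.  ``lmass`` accumulates total binned tract length
    per ancestry; whole-chromosome lengths accumulate separately by caller.
    Returns the number of whole-chromosome tracts.
    """
    nfull = 0
    B = edges.size
    for h in range(off.size - 1):
        i0 = off[h]
        i1 = off[h + 1]
        if i1 - i0 == 1:
            full[anc[i0]] += 1
            nfull += 1
            continue
        start = 0.0
        for i in range(i0, i1):
            ln = ends[i] - start
            start = ends[i]
            if ln < edges[0]:
                continue
            # linear scan ok: B small; find bin with edges[b] <= ln < edges[b+1]
            b = B - 1
            for j in range(1, B):
                if ln < edges[j]:
                    b = j - 1
                    break
            counts[anc[i], b] += 1
            lmass[anc[i]] += ln
    return nfull
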