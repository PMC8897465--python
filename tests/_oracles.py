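"""Independent brute-force oracles shared across test modules."""


def oracle_call_peaks(values, bin_size, origin, threshold, min_run, max_gap):
    """Plain-loop enumeration of the run/merge/filter peak rule."""
    enriched = [v >= threshold for v in values]
    runs = []
    i = 0
    while i < len(values):
        if enriched[i]:
            j = i
            while j < len(values) and enriched[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    merged = []
    for run in runs:
        if merged and (run[0] - merged[-1][1]) * bin_size <= max_gap:
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(run)
    out = []
    for s, e in merged:
        if (e - s) * bin_size < min_run:
            continue
        vals_in = [values[k] for k in range(s, e) if enriched[k]]
        out.append(
            (origin + s * bin_size, origin + e * bin_size, max(vals_in),
             len(vals_in))
        )
    return out


def as_tuples(ps):
    return [(p.start, p.end, p.max_value, p.n_enriched_bins) for p in ps]


def oracle_count(seq, motif, overlapping=True, both=True):
    """Sliding-window motif count with optional reverse complement."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc = "".join(comp[c] for c in reversed(motif))
    pats = [motif] + ([rc] if both and rc != motif else [])
    n = 0
    for pat in pats:
        i = 0
        while i + len(pat) <= len(seq):
            if seq[i : i + len(pat)] == pat:
                n += 1
                i += 1 if overlapping else len(pat)
            else:
                i += 1
    return n
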