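"""Call ChIP peaks, classify mitotic retention, and count GAGAG motifs.

Builds a synthetic binned ChIP/Input coverage pair with planted peaks
and a matching genome, normalizes, calls peaks with the threshold
caller (threshold 100, min run 50 bp, max gap 200 bp), classifies an
interphase/mitotic track pair, and counts GAGAG motifs per peak.
"""

from mitobook import chip_peaks, synthetic

chip, inp, genome, truth = synthetic.gen_coverage_and_genome(seed=1)
signal = chip_peaks.subtract_input(chip, inp)
peaks = chip_peaks.call_peaks(signal, threshold=100, min_run=50, max_gap=200)
print(f"called {len(peaks)} peaks ({len(truth.ground_truth['peaks'])} planted)")

motifs = chip_peaks.count_motif(peaks, genome, motif="GAGAG")
print(f"mean GAGAG motifs per peak: {motifs['count'].mean():.2f}")
# Peaks of a GAGA-factor-like ChIP carry (GA)_n arrays; the count is the
# number of (possibly overlapping) GAGAG matches on either strand.

inter, mito, design = synthetic.gen_interphase_mitotic_pair(
    n_retained=12, n_interphase_only=5, n_mitosis_only=3, seed=1
)
cls = chip_peaks.classify_peaks(
    chip_peaks.call_peaks(inter, 100, 50, 200),
    chip_peaks.call_peaks(mito, 100, 50, 200),
)
print("classification:", cls.counts())
# "mitotically retained" = interphase peaks sharing >= 1 bp with a
# mitotic peak - the bookmarking signature.
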