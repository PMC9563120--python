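"""Brute-force reference implementations used to cross-check the pipeline."""

import numpy as np


def oracle_top_two(trace, sched, min_height):
    """Independent peak-detection oracle: strict local maxima by neighbour
    comparison, then the top two per train window, ordered by time.

    Returns [(train_index, kind), ...] for comparison with detect_peaks.
    """
    f = trace.force
    locmax = [i for i in range(1, f.size - 1)
              if f[i] > f[i - 1] and f[i] >= f[i + 1] and f[i] >= min_height]
    windows = {}
    onsets = list(sched.onsets) + [np.inf]
    for i in locmax:
        t = trace.time[i]
        for k in range(len(sched)):
            if onsets[k] <= t < onsets[k + 1]:
                windows.setdefault(k, []).append((f[i], t))
    out = []
    for k in sorted(windows):
        ranked = sorted(windows[k], reverse=True)[:2]
        kinds = {vt: ("major" if vt == max(ranked) else "minor")
                 for vt in ranked}
        for vt in sorted(ranked, key=lambda vt: vt[1]):
            out.append((k, kinds[vt]))
    return out
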