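"""Independent brute-force oracles used to cross-check the package.

Everything here is written as literal, unoptimized loops translating the
stated rules directly, and must stay independent of the implementations it
checks.
"""

import math


def median_literal(values):
    s = sorted(values)
    n = len(s)
    if n % 2 == 1:
        return s[n // 2]
    return (s[n // 2 - 1] + s[n // 2]) / 2.0


def median_filter_literal(trace, window=5):
    half = window // 2
    out = []
    for i in range(len(trace)):
        lo = max(0, i - half)
        hi = min(len(trace), i + half + 1)
        out.append(median_literal(list(trace[lo:hi])))
    return out


def detect_events_literal(trace, median_window=5, mean_lookback=3, sd_lookback=10,
                          sd_multiplier=3.0, fixed_offset=0.15, persistence=5):
    """Literal nested-loop transcription of the shift-detection rule.

    A frame t is a call iff the filtered value at t and the ``persistence``
    following values are all strictly larger than the largest of
    (i) mean(previous mean_lookback) + sd_multiplier * sd(previous sd_lookback)
    (ii) mean(previous mean_lookback) + fixed_offset.
    Scanning resumes after the persistence window following a call.
    """
    n = len(trace)
    if n < sd_lookback + persistence + 1:
        return []
    f = median_filter_literal(trace, median_window)
    calls = []
    t = max(sd_lookback, mean_lookback)
    while t <= n - persistence - 1:
        prev_mean_frames = f[t - mean_lookback: t]
        mu = sum(prev_mean_frames) / len(prev_mean_frames)
        prev_sd_frames = f[t - sd_lookback: t]
        m10 = sum(prev_sd_frames) / len(prev_sd_frames)
        var = sum((x - m10) ** 2 for x in prev_sd_frames) / (len(prev_sd_frames) - 1)
        sd = math.sqrt(var)
        threshold = max(mu + sd_multiplier * sd, mu + fixed_offset)
        if all(f[t + i] > threshold for i in range(persistence + 1)):
            calls.append(t)
            t += persistence + 1
        else:
            t += 1
    return calls


def trace_from_events_literal(n_frames, baseline, events, decay_k, bleach_rate):
    """Noiseless trace from an event list: step + exponential decay,
    multiplied by cumulative per-frame bleaching."""
    out = []
    for t in range(n_frames):
        v = baseline
        for frame, magnitude in events:
            if t >= frame:
                v += magnitude * math.exp(-decay_k * (t - frame))
        out.append(v * (1.0 - bleach_rate) ** t)
    return out


def fourpl_literal(x, bottom, ic50, hill):
    return bottom + (1.0 - bottom) / (1.0 + 10 ** ((math.log10(ic50) - math.log10(x)) * hill))
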