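"""Independent, literal reference implementation of the three-step onset
detector, written with plain Python loops.  Used by unit and acceptance tests
to cross-check the packaged implementation; kept deliberately separate from
the package code path."""

import math


def oracle_detect(trace, times, smooth_width=5, half_height=0.5, angle_deg=5.0,
                  n_t=3, mode="dvalue", p_thres=None, detect_troughs=True):
    trace = [float(v) for v in trace]
    n = len(trace)
    if n < smooth_width + n_t:
        raise ValueError("trace too short")

    # Step 1: extremum
    if mode == "power":
        peak_idx = 0
        for i in range(n):
            if abs(trace[i]) > abs(trace[peak_idx]):
                peak_idx = i
        if p_thres is not None and abs(trace[peak_idx]) < p_thres:
            return math.nan
        if trace[peak_idx] < 0:
            if not detect_troughs:
                return math.nan
            trace = [-v for v in trace]
    else:
        peak_idx = 0
        for i in range(n):
            if trace[i] > trace[peak_idx]:
                peak_idx = i

    # Step 2: block smoothing, truncated at the edges
    halfw = smooth_width // 2
    smoothed = []
    for i in range(n):
        lo = max(0, i - halfw)
        hi = min(n - 1, i + (smooth_width - halfw - 1))
        smoothed.append(sum(trace[lo : hi + 1]) / (hi - lo + 1))

    peak = smoothed[peak_idx]
    if peak <= 0:
        return math.nan
    d_thres = peak * math.tan(math.radians(angle_deg))

    # Step 3: backward scan; persistence window = candidate and n_t-1 earlier bins
    for i in range(peak_idx - 1, -1, -1):
        if smoothed[i] >= half_height * peak:
            continue
        ok = True
        for j in range(i - n_t + 1, i + 1):
            if j < 1:
                ok = False
                break
            if abs(smoothed[j] - smoothed[j - 1]) >= d_thres:
                ok = False
                break
        if ok:
            return float(times[i])
    return math.nan
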