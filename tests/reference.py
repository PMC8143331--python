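"""Independent brute-force re-implementations used as test oracles.

Everything here is written directly from the trial-type and error
definitions with plain Python loops, sharing no code with the package's
scoring, filtering, or reliability modules. Deliberately slow and literal.
"""

from __future__ import annotations

import math


def brute_score(log):
    """Re-score one log from scratch: trial types, PE/SLE/IE, per-trial flags.

    Returns a dict with counts and the per-trial boolean lists.
    """
    exp = log.experimental
    fb = [bool(x) for x in exp.feedback]
    ap = [int(x) for x in exp.applied]
    pv = [int(x) for x in exp.prevailing]
    n = len(fb)

    base = ["unlabeled"] * n
    inference = [False] * n
    for t in range(1, n):
        base[t] = "repeat" if fb[t - 1] else "switch"
    for t in range(2, n):
        if base[t - 1] == "switch" and ap[t - 1] != ap[t - 2] and not fb[t - 1]:
            inference[t] = True

    pe = [False] * n
    sle = [False] * n
    ie = [False] * n
    for t in range(n):
        if base[t] == "switch" and ap[t] == ap[t - 1] and ap[t] != 3:
            pe[t] = True
        if base[t] == "repeat" and ap[t] != ap[t - 1]:
            sle[t] = True
        if inference[t] and ap[t] != pv[t]:
            ie[t] = True

    return {
        "n_trials": n,
        "n_switch": sum(b == "switch" for b in base),
        "n_repeat": sum(b == "repeat" for b in base),
        "n_inference": sum(inference),
        "pe": sum(pe),
        "sle": sum(sle),
        "ie": sum(ie),
        "base": base,
        "inference": inference,
        "pe_flags": pe,
        "sle_flags": sle,
        "ie_flags": ie,
    }


def brute_rt_mask(log, floor=100.0, ceiling_sd=3.0):
    """RT validity mask from scratch: floor, individual ceiling, error trials."""
    exp = log.experimental
    rt = [float(x) for x in exp.rt_ms]
    n = len(rt)
    s = brute_score(log)
    mean = sum(rt) / n
    sd = math.sqrt(sum((x - mean) ** 2 for x in rt) / (n - 1))
    cutoff = mean + ceiling_sd * sd
    return [
        rt[t] >= floor
        and rt[t] <= cutoff
        and not (s["pe_flags"][t] or s["sle_flags"][t] or s["ie_flags"][t])
        for t in range(n)
    ]


def brute_mean_rt(log, trial_type):
    """Mean RT of one trial type over brute-masked trials (nan if none)."""
    exp = log.experimental
    rt = [float(x) for x in exp.rt_ms]
    s = brute_score(log)
    mask = brute_rt_mask(log)
    if trial_type == "inference":
        sel = s["inference"]
    else:
        sel = [b == trial_type for b in s["base"]]
    xs = [rt[t] for t in range(len(rt)) if sel[t] and mask[t]]
    return sum(xs) / len(xs) if xs else float("nan")


def brute_half_score(log, in_a, measure):
    """Evaluate a measure on the half selected by ``in_a`` (list of bool)."""
    exp = log.experimental
    rt = [float(x) for x in exp.rt_ms]
    s = brute_score(log)
    n = s["n_trials"]
    if measure in ("pe", "sle", "ie"):
        flags = s[f"{measure}_flags"]
        return float(sum(1 for t in range(n) if flags[t] and in_a[t]))
    if measure.startswith("rt_"):
        kind = measure[3:]
        if kind == "inference":
            sel = s["inference"]
        else:
            sel = [b == kind for b in s["base"]]
        mask = brute_rt_mask(log)
        xs = [rt[t] for t in range(n) if sel[t] and mask[t] and in_a[t]]
        return sum(xs) / len(xs) if xs else float("nan")
    raise ValueError(measure)
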