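"""Independent reference implementations used as oracles by the test suite."""


def omega_squared_bruteforce(groups):
    """One-way ANOVA omega^2 (percent) via explicit loops over observations."""
    allv = [float(v) for g in groups for v in g]
    n, k = len(allv), len(groups)
    grand = sum(allv) / n
    ss_total = sum((v - grand) ** 2 for v in allv)
    ss_effect = 0.0
    for g in groups:
        gm = sum(g) / len(g)
        ss_effect += len(g) * (gm - grand) ** 2
    if ss_total == 0:
        return 0.0
    ms_error = (ss_total - ss_effect) / (n - k)
    return 100.0 * (ss_effect - (k - 1) * ms_error) / (ms_error + ss_total)
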