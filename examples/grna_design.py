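"""How many gRNAs are needed to keep the probability of resistance below 5%?

Evaluates the closed-form critical population sizes N* for the three
resistance pathways (NHEJ mutants, de novo SNPs, standing variation) and
inverts them for the minimal multiplexing level m at target population sizes
of 1e6 and 1e9, plus the amplification ratio N*_d / N*_s quantifying how much
weakly deleterious standing variation raises the risk over de novo mutation.
"""

from multidrive import (
    DriveParams,
    TheoryConstants,
    amplification_ratio,
    critical_N_combined,
    min_m_nhej,
    min_m_standing,
)

c = TheoryConstants()


def p(m=1, **kw):
    kw.setdefault("K", 1000)
    return DriveParams(m=m, **kw)


print("minimal m, NHEJ only (p <= 0.05):")
for N in (1e6, 1e9):
    ms = {b: min_m_nhej(N, 0.05, p(beta=b), c) for b in (1.0, 0.01, 1e-4)}
    print(f"  N={N:.0e}: " + ", ".join(f"beta={b:g} -> m={m}" for b, m in ms.items()))

print("minimal m, de novo + standing variation (xi=1, p <= 0.05):")
for N in (1e6, 1e9):
    ms = {s: min_m_standing(N, 0.05, p(sigma=s, xi=1.0), c) for s in (1e-6, 1e-4, 1e-2)}
    print(f"  N={N:.0e}: " + ", ".join(f"sigma={s:g} -> m={m}" for s, m in ms.items()))

print("amplification N*_d / N*_s (standing variation vs de novo):")
for sigma in (0.01, 1e-4):
    ratios = [amplification_ratio(m, sigma, c) for m in (1, 2, 3)]
    print(f"  sigma={sigma:g}: " + ", ".join(f"m={m}: {r:.3g}" for m, r in zip((1, 2, 3), ratios)))

combined = critical_N_combined(p(m=1, beta=1e-4, sigma=0.01, xi=1.0), c)
print(f"combined critical size (m=1, beta=1e-4, sigma=0.01): N* = {combined:.3g}")
# Large amplification ratios for m > 1 are the key design warning: a gRNA
# count chosen from de novo rates alone underestimates resistance risk when
# resistant standing variation is only weakly deleterious.
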