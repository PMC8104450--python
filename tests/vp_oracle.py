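"""Independent brute-force oracle for the boundary edit distance.

Enumerates every order-preserving matching between two boundary sets and
takes the cheapest total cost (matched pairs cost |dt|/tau; every unmatched
boundary costs 1).  Exponential, only for tiny sets — used to
validate the dynamic-programming implementation.
"""

from itertools import combinations


def vp_bruteforce(m, t, tau):
    m, t = list(m), list(t)
    best = float("inf")
    best_matches = 0
    kmax = min(len(m), len(t))
    for k in range(kmax + 1):
        for mi in combinations(range(len(m)), k):
            for ti in combinations(range(len(t)), k):
                cost = (len(m) - k) + (len(t) - k)
                matches = 0
                for a, b in zip(mi, ti):
                    c = abs(m[a] - t[b]) / tau
                    cost += c
                    if c < 1.0:
                        matches += 1
                if cost < best - 1e-12:
                    best = cost
                    best_matches = matches
                elif cost < best + 1e-12:
                    best_matches = max(best_matches, matches)
    return best, best_matches
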