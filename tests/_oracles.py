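"""Independent oracles for cross-checking the package.

Everything here is coded from the model's primitive formulas with its own
arithmetic (plain Python loops, no imports from vaxprice), so agreement with
the package is a genuine dual-route check and not a tautology.
"""

import itertools

S, I, R, D = 0, 1, 2, 3


def sird_path(s, i, r, d, delta, gamma, rho, taus, T):
    """Plain SIRD recursion with vaccination; returns list of (s, i, r, d) for t=0..T."""
    out = [(s, i, r, d)]
    for t in range(T):
        tau = taus[t] if t < len(taus) else taus[-1]
        s, i, r, d = (
            (1.0 - tau - delta * i) * s,
            (1.0 + delta * s - gamma - rho) * i,
            r + gamma * i + tau * s,
            d + rho * i,
        )
        out.append((s, i, r, d))
    return out


def q(prev, nxt, i_agg, tau, delta, gamma, rho):
    """One-period individual transition probability q_{t+1}(nxt | prev)."""
    if prev == S:
        return (1.0 - tau - delta * i_agg, delta * i_agg, tau, 0.0)[nxt]
    if prev == I:
        return (0.0, 1.0 - gamma - rho, gamma, rho)[nxt]
    if prev == R:
        return 1.0 if nxt == R else 0.0
    return 1.0 if nxt == D else 0.0


def enum_m(
    i_path,
    taus,
    delta,
    gamma,
    rho,
    *,
    w_S,
    w_I,
    d,
    beta,
    b=0.0,
    k=1.0,
    sigma=0.5,
    horizon=3,
    exclude_deceased=True,
    infected_excluded=False,
    c_floor=1e-3,
):
    """Pricing series m by exhaustive enumeration of all 4^omega health-state paths.

    ``i_path[j]`` and ``taus[j]`` are the aggregate infected share and the
    vaccination rate governing the transition from t+j to t+j+1, for an
    individual susceptible at t.  Power utility u'(c) = c^-sigma.
    """

    def uprime(c):
        return c ** (-sigma)

    def weighted_uprime(state):
        if state == D:
            return 0.0 if exclude_deceased else uprime(0.0)
        if state == I and infected_excluded:
            return uprime(c_floor)
        w = w_I if state == I else w_S
        return uprime(b + d * k + w)

    total = 0.0
    for omega in range(1, horizon + 1):
        for path in itertools.product(range(4), repeat=omega):
            prob = 1.0
            prev = S
            for j, state in enumerate(path):
                prob *= q(prev, state, i_path[j], taus[j], delta, gamma, rho)
                if prob == 0.0:
                    break
                prev = state
            if prob > 0.0:
                total += beta**omega * d * prob * weighted_uprime(path[-1])
    return total


def alive_probability(i_path, taus, delta, gamma, rho, horizon):
    """P(alive at t+omega | susceptible at t) for omega=1..horizon, by its own recursion."""
    dist = [1.0, 0.0, 0.0, 0.0]
    out = []
    for j in range(horizon):
        nxt = [0.0] * 4
        for prev in range(4):
            if dist[prev] == 0.0:
                continue
            for s2 in range(4):
                nxt[s2] += dist[prev] * q(prev, s2, i_path[j], taus[j], delta, gamma, rho)
        dist = nxt
        out.append(dist[S] + dist[I] + dist[R])
    return out
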