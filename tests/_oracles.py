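"""Independent reference implementations used only to check the package.

These deliberately share no code with petmine's implementations: the HMM
oracle enumerates every state path explicitly; the identity oracle is a
plain DP over match counts; the pI oracle is a dense grid scan.
"""

import numpy as np

from petmine.phmm import PHMMConfig, ProfileHMM


def random_profile_hmm(M: int, alphabet: str, rng: np.random.Generator) -> ProfileHMM:
    """A structurally valid random model over a small alphabet."""
    K = len(alphabet)

    def dist(n):
        v = rng.random(n) + 0.05
        return v / v.sum()

    match_emis = np.array([dist(K) for _ in range(M)])
    insert_emis = np.array([dist(K) for _ in range(M)])
    t_m = np.zeros((M, 4))
    t_i = np.zeros((M, 3))
    t_d = np.zeros((M, 3))
    for k in range(M):
        if k < M - 1:
            t_m[k] = dist(4)
            t_i[k] = dist(3)
            t_d[k] = dist(3)
        else:
            a = dist(2)
            t_m[k] = [0.0, a[0], 0.0, a[1]]   # I_M or E
            b = dist(2)
            t_i[k] = [b[0], b[1], 0.0]        # E (advance) or I_M
            c = dist(2)
            t_d[k] = [c[0], c[1], 0.0]
    return ProfileHMM(
        M=M, column_map=list(range(M)), match_emis=match_emis,
        insert_emis=insert_emis, t_m=t_m, t_i=t_i, t_d=t_d,
        background=np.full(K, 1.0 / K), alphabet=alphabet,
        config=PHMMConfig(),
    )


def enumerate_paths_prob(model: ProfileHMM, seq: str, mode: str = "sum") -> float:
    """Total (or max) path probability of a sequence by explicit enumeration."""
    M = model.M
    eta = model.eta
    idx = {a: i for i, a in enumerate(model.alphabet)}
    x = [idx[c] for c in seq]
    L = len(x)
    bg = model.background
    acc = {"total": 0.0, "best": 0.0}

    def done(p):
        if mode == "sum":
            acc["total"] += p
        else:
            acc["best"] = max(acc["best"], p)

    def from_C(i, p):
        while True:
            if i == L:
                done(p * (1.0 - eta))
                return
            p *= eta * bg[x[i]]
            i += 1

    def from_state(state, k, i, p):
        if p == 0.0:
            return
        if state == "M":
            if i >= L:
                return
            p *= model.match_emis[k - 1, x[i]]
            i += 1
            row = model.t_m[k - 1]
            if k < M:
                from_state("M", k + 1, i, p * row[0])
                from_state("I", k, i, p * row[1])
                from_state("D", k + 1, i, p * row[2])
                from_C(i, p * row[3])
            else:
                from_state("I", M, i, p * row[1])
                from_C(i, p * row[3])
        elif state == "I":
            if i >= L:
                return
            p *= model.insert_emis[k - 1, x[i]]
            i += 1
            row = model.t_i[k - 1]
            if k < M:
                from_state("M", k + 1, i, p * row[0])
                from_state("I", k, i, p * row[1])
                from_state("D", k + 1, i, p * row[2])
            else:
                from_C(i, p * row[0])   # advance from k=M is E
                from_state("I", M, i, p * row[1])
        elif state == "D":
            row = model.t_d[k - 1]
            if k < M:
                from_state("M", k + 1, i, p * row[0])
                from_state("I", k, i, p * row[1])
                from_state("D", k + 1, i, p * row[2])
            else:
                from_C(i, p * row[0])
                from_state("I", M, i, p * row[1])

    # N flank emits a prefix of any length, then uniform entry into a match state
    prefix_p = 1.0
    for n_flank in range(L + 1):
        enter = prefix_p * (1.0 - eta) / M
        for k in range(1, M + 1):
            from_state("M", k, n_flank, enter)
        if n_flank < L:
            prefix_p *= eta * bg[x[n_flank]]
        else:
            break
    return acc["total"] if mode == "sum" else acc["best"]


def oracle_bits(model: ProfileHMM, seq: str, mode: str = "sum") -> float:
    p = enumerate_paths_prob(model, seq, mode)
    eta = model.eta
    null = (1.0 - eta) * eta ** len(seq)
    for c in seq:
        null *= model.background[model.alphabet.index(c)]
    return float(np.log2(p) - np.log2(null))


def nw_identity(a: str, b: str) -> float:
    """Max matched positions over a global alignment (match 1, else 0) / shorter."""
    n, m = len(a), len(b)
    dp = np.zeros((n + 1, m + 1), dtype=int)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            dp[i, j] = max(
                dp[i - 1, j - 1] + (a[i - 1] == b[j - 1]),
                dp[i - 1, j],
                dp[i, j - 1],
            )
    return dp[n, m] / min(n, m)


def grid_pi(seq: str, step: float = 0.001) -> float:
    """Dense-grid sign-change search for the isoelectric point.

    Recomputes the Henderson-Hasselbalch charge directly from the pKa table
    (vectorized over the grid) rather than calling the package's charge
    function point by point.
    """
    from petmine.features import ConstantsTable

    pka = ConstantsTable.default().pka
    grid = np.arange(0.0, 14.0 + step, step)
    charges = np.zeros_like(grid)
    for key, count in [("n_terminus", 1), ("K", seq.count("K")),
                       ("R", seq.count("R")), ("H", seq.count("H"))]:
        charges += count / (1.0 + 10.0 ** (grid - pka[key]))
    for key, count in [("c_terminus", 1), ("D", seq.count("D")),
                       ("E", seq.count("E")), ("C", seq.count("C")),
                       ("Y", seq.count("Y"))]:
        charges -= count / (1.0 + 10.0 ** (pka[key] - grid))
    sign = np.signbit(charges)
    flips = np.nonzero(np.diff(sign.astype(int)) != 0)[0]
    if len(flips) == 0:
        return 0.0 if charges[0] < 0 else 14.0
    j = flips[0]
    return float((grid[j] + grid[j + 1]) / 2.0)
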