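"""Independent reference implementations used to check the optimized code.

Deliberately naive: full DP table, no bit tricks, no early exits.
"""


def dp_levenshtein(a: str, b: str) -> int:
    """Textbook full-table Wagner-Fischer edit distance."""
    m, n = len(a), len(b)
    table = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(m + 1):
        table[i][0] = i
    for j in range(n + 1):
        table[0][j] = j
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            table[i][j] = min(
                table[i - 1][j] + 1,
                table[i][j - 1] + 1,
                table[i - 1][j - 1] + cost,
            )
    return table[m][n]


def dp_lsim(a: str, b: str) -> float:
    return 1.0 - dp_levenshtein(a, b) / max(len(a), len(b))


def brute_force_components(n: int, edges: list[tuple[int, int]]) -> list[frozenset]:
    """Connected components by repeated closure (no union-find, no graph lib)."""
    groups = [{i} for i in range(n)]
    changed = True
    while changed:
        changed = False
        for u, v in edges:
            gu = next(g for g in groups if u in g)
            gv = next(g for g in groups if v in g)
            if gu is not gv:
                groups.remove(gv)
                gu |= gv
                changed = True
    return [frozenset(g) for g in groups]
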