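"""Independent brute-force oracles used only by the tests.

These deliberately re-derive results from first principles (truth-table
expression evaluation, linear scans, direct summation) without touching
the implementation's compiled-predicate path.
"""

from vasakit.records import VARecord


def eval_expr_oracle(node, record: VARecord) -> bool:
    """Recursive truth-table evaluation of a raw YAML expression node."""
    if "all" in node:
        return all(eval_expr_oracle(s, record) for s in node["all"])
    if "any" in node:
        return any(eval_expr_oracle(s, record) for s in node["any"])
    if "not" in node:
        return not eval_expr_oracle(node["not"], record)
    if "pregnancy_months_lt" in node or "pregnancy_months_ge" in node:
        m = record.pregnancy_duration
        if m is None:
            return False
        ok = True
        if "pregnancy_months_lt" in node:
            ok &= m < node["pregnancy_months_lt"]
        if "pregnancy_months_ge" in node:
            ok &= m >= node["pregnancy_months_ge"]
        return ok
    if "onset_day_lt" in node or "onset_day_ge" in node:
        d = record.illness_onset_day
        if d is None:
            return False
        ok = True
        if "onset_day_lt" in node:
            ok &= d < node["onset_day_lt"]
        if "onset_day_ge" in node:
            ok &= d >= node["onset_day_ge"]
        return ok
    sd = (record.maternal_sign(node["sign"]) if node.get("scope") == "maternal"
          else record.sign(node["sign"]))
    if sd.present != node.get("presence", "yes"):
        return False
    if "min_duration" in node:
        if sd.duration is None or sd.duration < node["min_duration"]:
            return False
    if "max_duration" in node:
        if sd.duration is None or sd.duration > node["max_duration"]:
            return False
    if "onset_order_le" in node:
        if sd.onset_order is None or sd.onset_order > node["onset_order_le"]:
            return False
    return True


def classify_oracle(record: VARecord, ruleset) -> tuple[str, list[str]]:
    """Brute-force primary + co-morbid selection: evaluate every raw
    rule expression, suppress possible tiers whose counterpart fired,
    then take the minimum hierarchy rank."""
    fired = {}
    for cause, rule in ruleset.rules.items():
        fired[cause] = eval_expr_oracle(rule.expr_source, record)
    eligible = []
    for cause, ok in fired.items():
        if not ok:
            continue
        rule = ruleset.rules[cause]
        if rule.tier == "possible" and fired.get(rule.counterpart):
            continue
        eligible.append(cause)
    if not eligible:
        return "unspecified", []
    ranked = sorted(eligible, key=ruleset.hierarchy.order.index)
    primary = ranked[0]
    comorbid = [c for c in ranked[1:] if ruleset.hierarchy.comorbid_ok[c]]
    return primary, comorbid


def pearson_chi2_oracle(x1, n1, x2, n2):
    """Textbook Pearson 2x2 chi-square (observed vs expected cells)."""
    obs = [[x1, n1 - x1], [x2, n2 - x2]]
    total = n1 + n2
    chi2 = 0.0
    for i, row_total in enumerate((n1, n2)):
        for j, col_total in enumerate((x1 + x2, total - x1 - x2)):
            exp = row_total * col_total / total
            if exp > 0:
                chi2 += (obs[i][j] - exp) ** 2 / exp
    return chi2


def kappa_oracle(a, b, c, d):
    n = a + b + c + d
    po = (a + d) / n
    p_yes1, p_yes2 = (a + b) / n, (a + c) / n
    pe = p_yes1 * p_yes2 + (1 - p_yes1) * (1 - p_yes2)
    return (po - pe) / (1 - pe)
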