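"""Independent brute-force trajectory oracle.

Deliberately written in plain scalar Python (dicts, lists, math) with
no code shared with the package, so it can serve as an independent
check of the model recursions and likelihood.
"""

import math


def oracle_trajectory(session, alpha_e, lam_e, beta_e, alpha_t, lam_t, beta_t,
                      window=5, skip_absent=False):
    """Step-by-step replay of a session; returns the probability
    assigned to each made choice (None for omissions)."""
    n_actions = 8
    v = {a: 0.0 for a in range(n_actions)}
    e = {a: 0.0 for a in range(n_actions)}
    q0 = {a: 0.0 for a in range(n_actions)}
    q2 = {a: 0.0 for a in range(n_actions)}
    hist_v = []   # decision-time snapshots, oldest first
    hist_q = []
    conjoint = session.condition.value == "conjoint"
    probs = []
    choices = []

    def zpool(cur_pair_vals, history):
        if window == 0 or not history:
            return cur_pair_vals
        recent = history if window is None else history[-window:]
        flat = [x for snap in recent for x in snap]
        m = sum(flat) / len(flat)
        var = sum((x - m) ** 2 for x in flat) / len(flat)
        s = math.sqrt(var)
        if s == 0.0:
            s = 1.0
        return [(x - m) / s for x in cur_pair_vals]

    for t, trial in enumerate(session.trials):
        a, b = trial.pair
        qsum = {k: q0[k] + q2[k] for k in q0}
        zv = zpool([v[a], v[b]], hist_v)
        zq = zpool([qsum[a], qsum[b]], hist_q)
        ua = beta_e * zv[0] + beta_t * zq[0]
        ub = beta_e * zv[1] + beta_t * zq[1]
        ea, eb = math.exp(ua), math.exp(ub)
        p_a = ea / (ea + eb)
        hist_v.append([v[k] for k in range(n_actions)])
        hist_q.append([qsum[k] for k in range(n_actions)])

        ch = trial.choice
        if ch is None:
            probs.append(None)
            for k in e:
                e[k] *= lam_e
            choices.append(None)
            continue
        probs.append(p_a if ch == a else 1.0 - p_a)
        fb = trial.feedback
        # eligibility: single PE on the displayed total
        delta = fb.total - v[ch]
        for k in e:
            e[k] *= lam_e
        e[ch] = 1.0
        for k in v:
            v[k] += alpha_e * delta * e[k]
        # tabular double update
        if conjoint:
            q0[ch] += alpha_t * (fb.total - q0[ch])
        else:
            if fb.immediate_component is not None or not skip_absent:
                r0 = fb.immediate_component if fb.immediate_component is not None else 0
                q0[ch] += alpha_t * (r0 - q0[ch])
        tm2 = choices[t - 2] if t >= 2 else None
        if tm2 is not None:
            if conjoint:
                q2[tm2] += alpha_t * lam_t * (fb.total - q2[tm2])
            else:
                if fb.delayed_component is not None or not skip_absent:
                    r2 = fb.delayed_component if fb.delayed_component is not None else 0
                    q2[tm2] += alpha_t * lam_t * (r2 - q2[tm2])
        choices.append(ch)
    return probs


def oracle_nll(session, *params, **kw):
    probs = oracle_trajectory(session, *params, **kw)
    return -sum(math.log(p) for p in probs if p is not None)
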