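import pytest

from dendricap import BooleanFunction, fbp_family, representatives


@pytest.fixture(scope="session")
def fam():
    return fbp_family()


@pytest.fixture(scope="session")
def reps4():
    return representatives(4)


def brute_force_monotone(n):
    """All monotone functions of n variables by filtering every table (n <= 4).

    Independent of the package's pair-construction enumerator: checks the
    defining property f(x) <= f(y) for x <= y directly.
    """
    out = []
    for t in range(1 << (1 << n)):
        ok = True
        for k in range(1 << n):
            if not (t >> k) & 1:
                continue
            for j in range(n):
                if not (k >> j) & 1 and not (t >> (k | (1 << j))) & 1:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            out.append(BooleanFunction(n, t))
    return out
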