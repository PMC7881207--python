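import numpy as np

from tsnet.expression_io import ExpressionMatrix


def random_expression(rng: np.random.Generator, n_probes: int, n_samples: int) -> ExpressionMatrix:
    probes = [f"P{i}" for i in range(n_probes)]
    samples = [f"s{i}" for i in range(n_samples)]
    return ExpressionMatrix(probes, samples, rng.normal(5.0, 2.0, size=(n_probes, n_samples)))
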