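"""Minimize a 5-dimensional sphere function with the Archimedes optimizer.

Each candidate is a material object with density, volume and acceleration;
early iterations explore by collisions, late ones settle toward the best
object.  The history printed below is the best-so-far objective value,
which is guaranteed non-increasing.
"""

import numpy as np

from cardiovault import AOAConfig, optimize

config = AOAConfig(dim=5, lower=[-5] * 5, upper=[5] * 5,
                   pop_size=30, max_iter=200, seed=1)
result = optimize(lambda z: float(z @ z), config)

print("best position:", np.round(result.best_position, 6))
print(f"best objective: {result.best_fitness:.3e}")
for t in (0, 49, 99, 199):
    print(f"  best-so-far after iteration {t + 1:3d}: {result.history[t]:.3e}")
print("A value near 0 at the final iteration means the optimizer located "
      "the sphere's global minimum at the origin.")
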