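"""Net effect of turbulence on larval prey requirements.

Turbulence raises encounter rates (it lengthens the searched cylinder) but
lowers pursuit success; at the parameterized swimming speeds the loss wins,
so starvation and satiation points rise monotonically with the dissipation
rate and the optimum is calm water.
"""

import larvaforage as lf

cfg = lf.calibrated_config()
larva = lf.get_builtin("herring")
env = lf.reference_conditions("herring")

table = lf.turbulence_response(larva, env, cfg,
                               epsilon_grid=[0.0] + [10.0**k for k in range(-10, -3)])
print(table.to_string(index=False,
                      formatters={"epsilon": "{:.0e}".format,
                                  "starvation": "{:.2f}".format,
                                  "satiation": "{:.2f}".format}))
# inf rows mark dissipation rates at which the turbulent velocity exceeds
# the corrigible maximum for every prey bin: pursuit always fails and no
# prey concentration can sustain the larva.
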