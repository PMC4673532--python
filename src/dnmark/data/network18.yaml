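# 18-node regulatory network stand-in (versioned; do not edit casually).
#
# Core: nodes 0-2, collectively self-activating via h(y) = y^2/(1+y^2)
#   dx_i/dt = P + offset + beta * h(mean of core) - x_i
# The offset places the saddle-node of the low-expression branch exactly at
# P = 0: it solves  g + beta*h(x) - x = 0,  beta*h'(x) - 1 = 0.
#
# Downstream: nodes 3-17, each driven by one parent (activation h(x_p) or
# repression 1/(1+x_p^2)) with unit linear decay; the Jacobian block is
# triangular, so these nodes never destabilize on their own.
n_vars: 18
core:
  beta: 4.0
  offset: 0.06352571742513967
downstream:
  parents: [0, 1, 2, 0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11]
  repress: [false, true, false, true, false, true, false, true, false, true,
            false, true, false, true, false]
  alpha:   [1.6, 1.2, 2.0, 0.8, 1.4, 1.0, 1.8, 0.9, 1.3, 1.1, 1.7, 0.7,
            1.5, 1.0, 1.2]
  basal:   [0.10, 0.25, 0.15, 0.30, 0.10, 0.20, 0.15, 0.25, 0.10, 0.30,
            0.20, 0.15, 0.10, 0.25, 0.20]
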