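# Delayed-rectifier potassium channel: four identical 2-state activation
# gates (n^4). Rates in 1/ms, voltages in mV.
name: k
subunits:
  - name: n
    count: 4
    alpha: {law: exp_linear, a: 0.01, b: 10.0, v0: -55.0}
    beta: {law: exponential, a: 0.125, b: -80.0, v0: -65.0}
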