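# Minimal 2-state (closed/open) scheme with constant rates, the kind of
# model used for ionotropic receptor gating; also a useful sanity fixture
# because all three stochastic descriptions coincide on it.
name: two_state
states: [closed, open]
open_state: open
transitions:
  - {from: closed, to: open, rate: {law: constant, a: 1.0}}
  - {from: open, to: closed, rate: {law: constant, a: 2.0}}
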