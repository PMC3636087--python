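# polyspec documentation

* [Methods](methods.md) — the design model, recovery statistics,
  structure measures, reversion energetics, synthetic study conditions,
  numerical choices and known limitations.
* `../README.md` — overview, install, worked example, reproducing the
  results.
* `../examples/` — one narrative script per capability.
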