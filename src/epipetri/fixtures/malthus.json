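{
 "schema": 1,
 "name": "malthus",
 "compartments": [
  "N"
 ],
 "parameters": {
  "Lambda": "rate",
  "mu": "rate"
 },
 "transitions": [
  {
   "name": "birth",
   "rate": "Lambda"
  },
  {
   "name": "death",
   "rate": "mu"
  }
 ],
 "arcs": [
  {
   "source": "birth",
   "target": "N"
  },
  {
   "source": "N",
   "target": "death"
  }
 ],
 "golden": {
  "ode": {
   "N": "Lambda - mu*N"
  },
  "flags": {}
 }
}
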