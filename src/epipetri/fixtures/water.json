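{
 "schema": 1,
 "name": "water",
 "compartments": [
  "H",
  "O",
  "W"
 ],
 "parameters": {
  "alpha": "rate"
 },
 "transitions": [
  {
   "name": "reaction",
   "rate": "alpha"
  }
 ],
 "arcs": [
  {
   "source": "H",
   "target": "reaction",
   "multiplicity": 2
  },
  {
   "source": "O",
   "target": "reaction"
  },
  {
   "source": "reaction",
   "target": "W"
  }
 ],
 "golden": {
  "ode": {
   "H": "-2*alpha*H^2*O",
   "O": "-alpha*H^2*O",
   "W": "alpha*H^2*O"
  },
  "flags": {}
 }
}
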