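{
 "schema": 1,
 "name": "sis",
 "compartments": [
  "S",
  "I"
 ],
 "parameters": {
  "beta": "rate",
  "alpha": "rate"
 },
 "transitions": [
  {
   "name": "infect",
   "rate": "beta"
  },
  {
   "name": "recover",
   "rate": "alpha"
  }
 ],
 "arcs": [
  {
   "source": "S",
   "target": "infect"
  },
  {
   "source": "I",
   "target": "infect"
  },
  {
   "source": "infect",
   "target": "I",
   "multiplicity": 2
  },
  {
   "source": "I",
   "target": "recover"
  },
  {
   "source": "recover",
   "target": "S"
  }
 ],
 "km_partition": {
  "susceptible": {
   "compartments": [
    "S"
   ],
   "transitions": []
  },
  "infection_process": {
   "compartments": [],
   "transitions": [
    "infect"
   ]
  },
  "infection": {
   "compartments": [
    "I"
   ],
   "transitions": [
    "recover"
   ]
  }
 },
 "dfe": {
  "mode": "keep-symbolic"
 },
 "golden": {
  "ode": {
   "S": "-beta*S*I + alpha*I",
   "I": "beta*S*I - alpha*I"
  },
  "F": [
   [
    "beta*S"
   ]
  ],
  "V": [
   [
    "alpha"
   ]
  ],
  "K": [
   [
    "beta*S/alpha"
   ]
  ],
  "R0": "beta*S/alpha",
  "flags": {
   "assumption7_clean": true,
   "single_nonzero_eigenvalue": true,
   "closed_population": true,
   "demographic": false
  }
 }
}
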