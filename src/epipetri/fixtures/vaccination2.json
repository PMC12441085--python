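{
 "schema": 1,
 "name": "vaccination2",
 "compartments": [
  "S",
  "I",
  "V"
 ],
 "parameters": {
  "Lambda": "rate",
  "mu": "rate",
  "beta": "rate",
  "gamma": "rate",
  "chi": "probability",
  "psi": "rate",
  "delta": "probability",
  "N": "quantity"
 },
 "transitions": [
  {
   "name": "birth",
   "rate": "Lambda"
  },
  {
   "name": "death_S",
   "rate": "mu"
  },
  {
   "name": "vaccinate",
   "rate": "psi"
  },
  {
   "name": "infect_s",
   "rate": "beta/N"
  },
  {
   "name": "infect_v",
   "rate": "beta*delta/N"
  },
  {
   "name": "recover",
   "rate": "gamma"
  },
  {
   "name": "death_I",
   "rate": "mu"
  },
  {
   "name": "death_V",
   "rate": "mu"
  }
 ],
 "arcs": [
  {
   "source": "birth",
   "target": "S"
  },
  {
   "source": "S",
   "target": "death_S"
  },
  {
   "source": "S",
   "target": "vaccinate"
  },
  {
   "source": "vaccinate",
   "target": "V"
  },
  {
   "source": "S",
   "target": "infect_s"
  },
  {
   "source": "I",
   "target": "infect_s"
  },
  {
   "source": "infect_s",
   "target": "I",
   "multiplicity": 2
  },
  {
   "source": "V",
   "target": "infect_v"
  },
  {
   "source": "I",
   "target": "infect_v"
  },
  {
   "source": "infect_v",
   "target": "I",
   "multiplicity": 2
  },
  {
   "source": "I",
   "target": "recover"
  },
  {
   "source": "recover",
   "target": "S",
   "weight": "chi"
  },
  {
   "source": "recover",
   "target": "V",
   "weight": "1-chi"
  },
  {
   "source": "I",
   "target": "death_I"
  },
  {
   "source": "V",
   "target": "death_V"
  }
 ],
 "km_partition": {
  "susceptible": {
   "compartments": [
    "S",
    "V"
   ],
   "transitions": [
    "birth",
    "death_S",
    "vaccinate",
    "death_V"
   ]
  },
  "infection_process": {
   "compartments": [],
   "transitions": [
    "infect_s",
    "infect_v"
   ]
  },
  "infection": {
   "compartments": [
    "I"
   ],
   "transitions": [
    "recover",
    "death_I"
   ]
  }
 },
 "dfe": {
  "mode": "symbolic-solve",
  "substitutions": {
   "N": "Lambda/mu"
  }
 },
 "golden": {
  "ode": {
   "S": "Lambda - beta*S*I/N - (mu+psi)*S + chi*gamma*I",
   "I": "beta*S*I/N + beta*delta*V*I/N - (mu+gamma)*I",
   "V": "psi*S - beta*delta*V*I/N + (1-chi)*gamma*I - mu*V"
  },
  "F": [
   [
    "beta*mu/(mu+psi) + beta*delta*psi/(mu+psi)"
   ]
  ],
  "V": [
   [
    "mu+gamma"
   ]
  ],
  "K": [
   [
    "beta*(mu+delta*psi)/((mu+gamma)*(mu+psi))"
   ]
  ],
  "R0": "beta*(mu+delta*psi)/((mu+gamma)*(mu+psi))",
  "flags": {
   "assumption7_clean": true,
   "single_nonzero_eigenvalue": true,
   "closed_population": false,
   "demographic": true
  }
 }
}
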