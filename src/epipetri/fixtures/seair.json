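{
 "schema": 1,
 "name": "seair",
 "compartments": [
  "S",
  "E",
  "A",
  "I",
  "R"
 ],
 "parameters": {
  "Lambda": "rate",
  "mu": "rate",
  "beta": "rate",
  "q": "probability",
  "eta": "rate",
  "p": "probability",
  "gamma": "rate",
  "alpha": "rate"
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
   "name": "infect",
   "rate": "beta"
  },
  {
   "name": "infect_a",
   "rate": "q*beta"
  },
  {
   "name": "progress",
   "rate": "eta"
  },
  {
   "name": "recover_a",
   "rate": "gamma"
  },
  {
   "name": "recover_i",
   "rate": "alpha"
  },
  {
   "name": "death_E",
   "rate": "mu"
  },
  {
   "name": "death_A",
   "rate": "mu"
  },
  {
   "name": "death_I",
   "rate": "mu"
  },
  {
   "name": "death_R",
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
   "target": "infect"
  },
  {
   "source": "I",
   "target": "infect"
  },
  {
   "source": "infect",
   "target": "E"
  },
  {
   "source": "infect",
   "target": "I"
  },
  {
   "source": "S",
   "target": "infect_a"
  },
  {
   "source": "A",
   "target": "infect_a"
  },
  {
   "source": "infect_a",
   "target": "E"
  },
  {
   "source": "infect_a",
   "target": "A"
  },
  {
   "source": "E",
   "target": "progress"
  },
  {
   "source": "progress",
   "target": "A",
   "weight": "1-p"
  },
  {
   "source": "progress",
   "target": "I",
   "weight": "p"
  },
  {
   "source": "A",
   "target": "recover_a"
  },
  {
   "source": "recover_a",
   "target": "R"
  },
  {
   "source": "I",
   "target": "recover_i"
  },
  {
   "source": "recover_i",
   "target": "R"
  },
  {
   "source": "E",
   "target": "death_E"
  },
  {
   "source": "A",
   "target": "death_A"
  },
  {
   "source": "I",
   "target": "death_I"
  },
  {
   "source": "R",
   "target": "death_R"
  }
 ],
 "km_partition": {
  "susceptible": {
   "compartments": [
    "S"
   ],
   "transitions": [
    "birth",
    "death_S"
   ]
  },
  "infection_process": {
   "compartments": [],
   "transitions": [
    "infect",
    "infect_a"
   ]
  },
  "infection": {
   "compartments": [
    "E",
    "A",
    "I"
   ],
   "transitions": [
    "progress",
    "recover_a",
    "recover_i",
    "death_E",
    "death_A",
    "death_I"
   ]
  }
 },
 "dfe": {
  "mode": "keep-symbolic"
 },
 "golden": {
  "ode": {
   "S": "Lambda - beta*S*(I+q*A) - mu*S",
   "E": "beta*S*(I+q*A) - (eta+mu)*E",
   "A": "(1-p)*eta*E - (gamma+mu)*A",
   "I": "p*eta*E - (alpha+mu)*I",
   "R": "alpha*I + gamma*A - mu*R"
  },
  "F": [
   [
    "0",
    "beta*q*S",
    "beta*S"
   ],
   [
    "0",
    "0",
    "0"
   ],
   [
    "0",
    "0",
    "0"
   ]
  ],
  "V": [
   [
    "eta+mu",
    "0",
    "0"
   ],
   [
    "eta*(p-1)",
    "gamma+mu",
    "0"
   ],
   [
    "-eta*p",
    "0",
    "alpha+mu"
   ]
  ],
  "K": [
   [
    "beta*eta*(1-p)*q*S/((eta+mu)*(gamma+mu)) + beta*eta*p*S/((eta+mu)*(alpha+mu))",
    "beta*q*S/(gamma+mu)",
    "beta*S/(alpha+mu)"
   ],
   [
    "0",
    "0",
    "0"
   ],
   [
    "0",
    "0",
    "0"
   ]
  ],
  "R0": "beta*eta*(1-p)*q*S/((eta+mu)*(gamma+mu)) + beta*eta*p*S/((eta+mu)*(alpha+mu))",
  "flags": {
   "assumption7_clean": true,
   "single_nonzero_eigenvalue": true,
   "closed_population": false,
   "demographic": true
  }
 }
}
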