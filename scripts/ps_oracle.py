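"""Independent high-precision evaluation of the Petrov-Schwille formula.

Evaluates the explicit HPW approximation with exact rational constants and
50-digit arithmetic (sympy), entirely separately from the package's
floating-point implementation.  The values printed here are frozen as
regression fixtures in tests/test_hydrodynamics.py and
tests/test_acceptance.py.

Run:  python scripts/ps_oracle.py
"""
import sympy as sp

kB = sp.Rational(1380649, 10**6) * sp.Integer(10)**-23  # exact SI J/K
gamma = sp.EulerGamma
C1 = sp.Rational(73761, 100000)
b1 = sp.Rational(274819, 100000)
C2 = sp.Rational(52119, 100000)
b2 = sp.Rational(51465, 100000)

def D_ps(a, eta, mu1, mu2, T):
    eps = a * (mu1 + mu2) / eta
    L = sp.log(2 / eps)
    num = L - gamma + 4 * eps / sp.pi - (eps**2 / 2) * L
    den = 1 - (eps**3 / sp.pi) * L + C1 * eps**b1 / (1 + C2 * eps**b2)
    return (kB * T / (4 * sp.pi * eta)) * num / den

def D_sd(a, eta, mu1, mu2, T):
    eps = a * (mu1 + mu2) / eta
    return (kB * T / (4 * sp.pi * eta)) * (sp.log(2 / eps) - gamma)

# fixture condition: a=5 um, eta=1e-6 Pa s m, air/water bulk phases, 294 K
a, eta, mu1, mu2, T = (sp.Rational(5, 10**6), sp.Integer(10)**-6,
                       sp.Rational(18, 10**6), sp.Rational(98, 10**5),
                       sp.Integer(294))
eps = a*(mu1+mu2)/eta
print("fixture eps =", sp.nsimplify(eps), "=", sp.N(eps, 20))
d = D_ps(a, eta, mu1, mu2, T)
print("fixture D_ps [m^2/s] =", sp.N(d, 25))
print("fixture D_ps [um^2/s] =", sp.N(d * 10**12, 25))

# small-eps agreement: choose eta so eps=1e-3 with a=5um, mu1+mu2=9.98e-4
eta2 = a*(mu1+mu2)/sp.Rational(1,1000)
dps = D_ps(a, eta2, mu1, mu2, T)
dsd = D_sd(a, eta2, mu1, mu2, T)
print("eps=1e-3: eta =", sp.N(eta2,10), " D_ps/D_sd - 1 =", sp.N(dps/dsd - 1, 10))

# SD identity case: eps such that ln(2/eps)-gamma = 1 -> eps = 2*exp(-1-gamma)
epsid = 2*sp.exp(-1-gamma)
print("eps for SD identity =", sp.N(epsid, 20))
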