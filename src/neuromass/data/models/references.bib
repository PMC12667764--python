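@article{JansenRit1995,
  author  = {Jansen, Ben H. and Rit, Vincent G.},
  title   = {Electroencephalogram and visual evoked potential generation in a
             mathematical model of coupled cortical columns},
  journal = {Biological Cybernetics},
  volume  = {73},
  pages   = {357--366},
  year    = {1995}
}

@article{Grimbert2006,
  author  = {Grimbert, Fran{\c{c}}ois and Faugeras, Olivier},
  title   = {Bifurcation analysis of Jansen's neural mass model},
  journal = {Neural Computation},
  volume  = {18},
  number  = {12},
  pages   = {3052--3068},
  year    = {2006}
}

@article{WongWang2006,
  author  = {Wong, Kong-Fatt and Wang, Xiao-Jing},
  title   = {A recurrent network mechanism of time integration in perceptual
             decisions},
  journal = {Journal of Neuroscience},
  volume  = {26},
  number  = {4},
  pages   = {1314--1328},
  year    = {2006}
}

@article{Deco2014,
  author  = {Deco, Gustavo and Ponce-Alvarez, Adri{\'a}n and Hagmann, Patric
             and Romani, Gian Luca and Mantini, Dante and Corbetta, Maurizio},
  title   = {How local excitation-inhibition ratio impacts the whole brain
             dynamics},
  journal = {Journal of Neuroscience},
  volume  = {34},
  number  = {23},
  pages   = {7886--7898},
  year    = {2014}
}

@article{FitzHugh1961,
  author  = {FitzHugh, Richard},
  title   = {Impulses and physiological states in theoretical models of nerve
             membrane},
  journal = {Biophysical Journal},
  volume  = {1},
  number  = {6},
  pages   = {445--466},
  year    = {1961}
}

@article{SanzLeon2015,
  author  = {Sanz-Leon, Paula and Knock, Stuart A. and Spiegler, Andreas and
             Jirsa, Viktor K.},
  title   = {Mathematical framework for large-scale brain network modeling in
             The Virtual Brain},
  journal = {NeuroImage},
  volume  = {111},
  pages   = {385--430},
  year    = {2015}
}

@incollection{Kuramoto1975,
  author    = {Kuramoto, Yoshiki},
  title     = {Self-entrainment of a population of coupled non-linear
               oscillators},
  booktitle = {International Symposium on Mathematical Problems in Theoretical
               Physics},
  pages     = {420--422},
  publisher = {Springer},
  year      = {1975}
}
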