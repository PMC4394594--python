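taxon,AR,M,ar_annotation
Accipiter cooperii,5.63,0.558,
Accipiter gentilis,6.23,0.737,
Accipiter nisus,5.81,0.196,
Accipiter striatus,5.66,0.139,
Anas crecca,7.96,0.23,
Anas georgica,7.20,0.437,
Anas penelope,8.15,0.77,
Anas platyrhynchos,7.43,1.09,
Anhinga anhinga,7.65,0.96,
Anser albifrons,7.86,2.34,
Anser anser,7.70,3.65,
Anser indicus,8.24,2.44,
Ardea cinerea,7.15,1.21,
Ardea herodias,8.46,1.65,
Caracara plancus,6.83,1.3,
Cathartes aura,7.46,1.64,
Chionis albus,6.44,0.61,
Ciconia abdimii,7.00,1.03,
Coccyzus americanus,6.37,0.059,
Columba palumbus,7.08,0.495,
Diomedea exulans,15.0,7.98,
Falco columbarius,7.01,0.157,
Falco mexicanus,7.64,0.837,
Falco peregrinus,8.33,0.798,
Falco rusticolus,7.88,1.17,
Falco sparverius,7.70,0.084,
Fregata magnificens,11.5,1.39,
Fulmarus glacialis,10.5,0.824,
Gavia immer,9.97,3.58,
Gavia stellata,10.3,2.31,
Gyps africanus,6.88,5.5,
Gyps rueppellii,7.01,7.3,
Haematopus ostralegus,8.19,0.46,
Limnodromus griseus,8.32,0.061,
Megascops asio,5.87,0.098,
Mergus serrator,9.64,0.46,
Oceanites oceanicus,7.27,0.034,
Pachyptila desolata,8.60,0.155,
Pachyptila turtur,9.33,0.132,
Passer domesticus,4.80,0.029,
Pelecanoides georgicus,7.66,0.122,
Pelecanoides urinatrix,7.43,0.133,
Pelecanus erythrorhynchos,9.05,5.09,
Pelecanus occidentalis,10.8,2.66,
Pelecanus onocrotalus,8.76,7.3,
Pelecanus rufescens,7.64,4.8,
Phaethon aethereus,10.8,0.65,
Phaethon lepturus,10.0,0.37,
Phaethon rubricauda,11.2,0.65,
Phalacrocorax aristotelis,6.90,1.642,
Phalacrocorax atriceps,6.98,2.23,
Phalacrocorax auritus,7.58,1.28,
Phalacrocorax carbo,8.52,2.53,
Phasianus colchicus,5.21,1.2,
Platalea ajaja,6.91,1.3,
Plegadis chihi,6.78,0.418,
Puffinus huttoni,11.2,0.364,
Puffinus lherminieri,9.94,0.15,
Puffinus nativitatis,9.61,0.34,
Puffinus pacificus,10.2,0.38,
Puffinus tenuirostris,12.1,0.544,
Rallus longirostris,5.10,0.22,
Rissa tridactyla,9.21,0.394,
Stercorarius parasiticus,9.85,0.419,
Sterna maxima,12.2,0.256,
Sula dactylatra,12.2,1.9,
Sula leucogaster,11.9,0.938,
Sula sula,11.2,1.1,
Tyto alba,7.23,0.38,
Uria aalge,9.34,0.831,
Zenaida macroura,5.94,0.098,
Ichthyornis dispar,,,
Eocypselus rowei,,,8.15
Parargornis messelensis,,,5.30
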