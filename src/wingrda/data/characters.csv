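taxon,drp,crp,dpf,iip1,iip2,fp,extinct
Accipiter cooperii,1,0,1,1,0,1,0
Accipiter gentilis,1,0,1,1,0,1,0
Accipiter nisus,1,0,1,1,0,1,0
Accipiter striatus,1,0,1,1,0,1,0
Anas crecca,1,0,0,0,0,1,0
Anas georgica,1,0,0,0,0,1,0
Anas penelope,1,0,0,0,0,1,0
Anas platyrhynchos,1,0,0,0,0,1,0
Anhinga anhinga,1,1,0,1,0,1,0
Anser albifrons,1,0,0,0,0,1,0
Anser anser,1,0,0,0,0,1,0
Anser indicus,1,0,0,0,0,1,0
Ardea cinerea,2,0,0,1,0,1,0
Ardea herodias,2,0,0,1,0,1,0
Caracara plancus,2,0,1,1,0,2,0
Cathartes aura,2,1,0,1,0,2,0
Chionis albus,1,1,1,1,0,2,0
Ciconia abdimii,1,0,0,1,0,1,0
Coccyzus americanus,2,1,1,1,0,1,0
Columba palumbus,1,0,1,1,0,1,0
Diomedea exulans,1,1,0,1,1,1,0
Falco columbarius,1,0,1,1,0,2,0
Falco mexicanus,1,0,1,1,0,2,0
Falco peregrinus,1,0,1,1,0,2,0
Falco rusticolus,1,0,1,1,0,2,0
Falco sparverius,1,0,1,1,0,2,0
Fregata magnificens,2,1,2,1,1,2,0
Fulmarus glacialis,1,0,1,1,1,1,0
Gavia immer,1,1,0,1,0,1,0
Gavia stellata,1,1,0,1,0,1,0
Gyps africanus,1,1,0,1,1,2,0
Gyps rueppellii,1,1,0,1,1,2,0
Haematopus ostralegus,1,1,0,1,0,2,0
Limnodromus griseus,2,1,1,1,1,1,0
Megascops asio,1,0,1,1,0,1,0
Mergus serrator,1,1,0,0,0,1,0
Oceanites oceanicus,1,1,0,1,0,1,0
Pachyptila desolata,1,1,0,1,0,1,0
Pachyptila turtur,1,1,0,1,0,1,0
Passer domesticus,1,0,0,1,0,1,0
Pelecanoides georgicus,1,1,0,1,0,1,0
Pelecanoides urinatrix,1,1,0,1,0,1,0
Pelecanus erythrorhynchos,2,1,1,1,1,2,0
Pelecanus occidentalis,2,1,1,1,1,2,0
Pelecanus onocrotalus,2,1,1,1,1,2,0
Pelecanus rufescens,2,1,1,1,1,2,0
Phaethon aethereus,2,1,1,1,1,1,0
Phaethon lepturus,2,1,1,1,1,1,0
Phaethon rubricauda,2,1,1,1,1,1,0
Phalacrocorax aristotelis,1,1,0,1,0,1,0
Phalacrocorax atriceps,1,1,0,1,0,1,0
Phalacrocorax auritus,1,1,0,1,0,1,0
Phalacrocorax carbo,1,1,0,1,0,1,0
Phasianus colchicus,1,0,0,0,0,1,0
Platalea ajaja,2,1,0,1,0,1,0
Plegadis chihi,2,1,0,1,0,1,0
Puffinus huttoni,1,1,0,1,0,1,0
Puffinus lherminieri,1,1,0,1,0,1,0
Puffinus nativitatis,1,1,0,1,0,1,0
Puffinus pacificus,1,1,0,1,0,1,0
Puffinus tenuirostris,1,1,0,1,0,1,0
Rallus longirostris,1,0,0,0,0,1,0
Rissa tridactyla,1,1,2,1,1,1,0
Stercorarius parasiticus,1,1,2,1,1,1,0
Sterna maxima,2,0,2,1,1,1,0
Sula dactylatra,1,0,1,1,1,1,0
Sula leucogaster,1,0,1,1,1,1,0
Sula sula,1,0,1,1,1,1,0
Tyto alba,1,0,1,1,0,1,0
Uria aalge,1,0,1,1,0,1,0
Zenaida macroura,1,0,1,1,0,1,0
Ichthyornis dispar,1,0,1,1,0,1,1
Eocypselus rowei,0,0,1,1,0,0,1
Parargornis messelensis,0,0,1,1,0,0,1
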